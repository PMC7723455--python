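"""Physical constants and the order-parameter definition.

The central quantity of the package is the molecular order parameter

    S = D_exp / D_rigid,

the ratio of a motionally averaged heteronuclear dipolar coupling to its
rigid-limit value.  S runs from 0 (isotropic mobility) to 1 (complete
rigidity).  The rigid limit is computed from the point-dipole expression

    D_rigid = (mu0 / 8 pi^2) * gamma_I * gamma_S * hbar / r^3   [Hz]

with an effective (vibrationally averaged) internuclear distance.  During
the dipolar evolution period of a separated-local-field experiment the
proton bath is decoupled homonuclearly, which scales the heteronuclear
coupling by a known factor kappa (1/sqrt(3) for Lee-Goldburg irradiation);
the coupling that actually evolves is therefore

    d_eff = kappa * S * D_rigid.

All couplings in this package are in Hz; factors of 2 pi appear only
inside phase computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import constants

__all__ = [
    "GAMMA_H1",
    "GAMMA_C13",
    "DEFAULT_R_EFF_ANGSTROM",
    "KAPPA_FSLG",
    "SpinPair",
    "DecouplingScale",
    "OrderParameter",
    "rigid_limit_coupling",
    "order_parameter",
    "effective_coupling",
    "one_bond_ch",
    "fslg",
]

#: 1H gyromagnetic ratio, rad s^-1 T^-1 (CODATA).
GAMMA_H1: float = constants.value("proton gyromag. ratio")

#: 13C gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_C13: float = 6.728284e7

#: Effective one-bond C-H distance in Angstrom (vibrationally averaged).
#: Yields a rigid-limit coupling of ~21.7 kHz; literature conventions span
#: roughly 21.5-23.3 kHz, so this is exposed as configuration, not buried.
DEFAULT_R_EFF_ANGSTROM: float = 1.117

#: Theoretical Lee-Goldburg homonuclear-decoupling scale factor.
KAPPA_FSLG: float = 1.0 / math.sqrt(3.0)


def _point_dipole_hz(gamma_i: float, gamma_s: float, r_angstrom: float) -> float:
    r_m = r_angstrom * 1e-10
    return constants.mu_0 / (8.0 * math.pi**2) * gamma_i * gamma_s * constants.hbar / r_m**3


@dataclass(frozen=True)
class SpinPair:
    """A heteronuclear spin pair defining the rigid-limit dipolar coupling.

    Parameters
    ----------
    gamma_I, gamma_S:
        Gyromagnetic ratios of the abundant (I) and observed (S) nucleus,
        in rad s^-1 T^-1.
    r_eff:
        Effective internuclear distance in Angstrom; must be positive.
    d_rigid_override:
        Optional explicit rigid-limit coupling in Hz.  When given it takes
        precedence over the value computed from ``r_eff`` (some labs quote
        a calibrated rigid limit rather than a bond length).
    """

    gamma_I: float = GAMMA_H1
    gamma_S: float = GAMMA_C13
    r_eff: float = DEFAULT_R_EFF_ANGSTROM
    d_rigid_override: float | None = None
    d_rigid: float = field(init=False)

    def __post_init__(self) -> None:
        if self.r_eff <= 0:
            raise ValueError(f"r_eff must be positive, got {self.r_eff}")
        if self.d_rigid_override is not None:
            if self.d_rigid_override <= 0:
                raise ValueError("d_rigid_override must be positive")
            d = float(self.d_rigid_override)
        else:
            d = _point_dipole_hz(self.gamma_I, self.gamma_S, self.r_eff)
        object.__setattr__(self, "d_rigid", d)


@dataclass(frozen=True)
class DecouplingScale:
    """Scaling of the heteronuclear coupling under homonuclear decoupling."""

    kappa: float = KAPPA_FSLG
    scheme_name: str = "FSLG"

    def __post_init__(self) -> None:
        if not 0.0 < self.kappa <= 1.0:
            raise ValueError(f"kappa must be in (0, 1], got {self.kappa}")


@dataclass(frozen=True)
class OrderParameter:
    """A dimensionless order parameter with uncertainty and a label."""

    S: float
    sigma_S: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.S <= 1.0:
            raise ValueError(f"S must lie in [0, 1], got {self.S}")
        if self.sigma_S < 0:
            raise ValueError("sigma_S must be non-negative")


def rigid_limit_coupling(pair: SpinPair) -> float:
    """Rigid-limit dipolar coupling of ``pair`` in Hz."""
    return pair.d_rigid


def order_parameter(
    d_exp: float,
    d_rigid: float,
    label: str = "",
    sigma_S: float = 0.0,
    tol: float = 1e-6,
) -> OrderParameter:
    """Convert a motionally averaged coupling to an order parameter.

    Raises
    ------
    ValueError
        If ``d_rigid`` is not positive, ``d_exp`` is negative, or
        ``d_exp`` exceeds ``d_rigid`` beyond ``tol`` (a coupling larger
        than the rigid limit signals a miscalibrated rigid-limit
        convention, not motion).
    """
    if d_rigid <= 0:
        raise ValueError("d_rigid must be positive")
    if d_exp < 0:
        raise ValueError("d_exp must be non-negative")
    s = d_exp / d_rigid
    if s > 1.0 + tol:
        raise ValueError(
            f"d_exp/d_rigid = {s:.4f} > 1: rigid-limit convention suspect"
        )
    return OrderParameter(S=min(s, 1.0), sigma_S=sigma_S, label=label)


def effective_coupling(S: float, pair: SpinPair, scale: DecouplingScale) -> float:
    """Coupling evolving during t1: ``kappa * S * d_rigid`` in Hz."""
    if not 0.0 <= S <= 1.0:
        raise ValueError(f"S must lie in [0, 1], got {S}")
    return scale.kappa * S * pair.d_rigid


def one_bond_ch(r_eff: float = DEFAULT_R_EFF_ANGSTROM,
                d_rigid_override: float | None = None) -> SpinPair:
    """Convenience constructor for the default 1H-13C one-bond pair."""
    return SpinPair(r_eff=r_eff, d_rigid_override=d_rigid_override)


def fslg(kappa: float = KAPPA_FSLG) -> DecouplingScale:
    """Convenience constructor for the FSLG decoupling scale."""
    return DecouplingScale(kappa=kappa, scheme_name="FSLG")
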