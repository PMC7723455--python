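"""DIPSHIFT dipolar dephasing curves under magic-angle spinning.

Under MAS the heteronuclear dipolar interaction of a single I-S pair is
modulated at the rotor frequency.  For a crystallite with powder angles
(beta, gamma) the instantaneous dipolar frequency during t1 evolution is

    omega(t) = 2 pi d_eff [ c1(beta) cos(w_r t + gamma)
                          + c2(beta) cos(2 w_r t + 2 gamma) ]

with c1 = (sqrt(2)/2) sin(2 beta), c2 = -(1/2) sin^2(beta) and
w_r = 2 pi nu_r.  The accumulated phase Phi(t1) is the time integral of
omega, available in closed form because both terms are pure rotor
harmonics; consequently Phi(tau_r) = 0 for every orientation — the signal
refocuses exactly after a full rotor period.  The observable dephasing
curve is the powder average of cos(Phi(t1)).

Because Phi is linear in d_eff, a single "unit phase" array (phase per Hz
of effective coupling, per orientation and t1 point) serves every coupling
strength on a given grid; it is cached on the powder scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MASCondition",
    "PowderScheme",
    "DephasingCurve",
    "ConvergenceWarning",
    "dipolar_phase",
    "dephasing_curve",
    "dephasing_depth",
    "default_powder",
]


class ConvergenceWarning(UserWarning):
    """Raised/warned when the powder average has not converged."""


@dataclass(frozen=True)
class MASCondition:
    """MAS frequency and the t1 evolution grid within one rotor period."""

    nu_r: float
    t1_grid: np.ndarray

    def __post_init__(self) -> None:
        if self.nu_r <= 0:
            raise ValueError(f"nu_r must be positive, got {self.nu_r}")
        grid = np.asarray(self.t1_grid, dtype=float)
        object.__setattr__(self, "t1_grid", grid)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("t1_grid must be a 1-D array with >= 2 points")
        if grid[0] != 0.0:
            raise ValueError("t1_grid must start at 0")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("t1_grid must be strictly ascending")
        if grid[-1] > self.tau_r * (1 + 1e-12):
            raise ValueError("t1_grid must stay within one rotor period")

    @property
    def tau_r(self) -> float:
        """Rotor period in seconds."""
        return 1.0 / self.nu_r

    @classmethod
    def evenly_spaced(cls, nu_r: float, n_points: int = 9) -> "MASCondition":
        """Inclusive grid of ``n_points`` delays spanning [0, tau_r].

        Nine points is the default increment count; seven is the common
        alternative.  Both endpoints are included so the full-rotor
        refocusing point is part of every curve.
        """
        if n_points < 2:
            raise ValueError("need at least 2 increments")
        return cls(nu_r=nu_r, t1_grid=np.linspace(0.0, 1.0 / nu_r, n_points))


@dataclass
class PowderScheme:
    """Deterministic (beta, gamma) orientation grid with sin(beta) weights.

    beta is taken at cell midpoints in [0, pi] so the weight never
    vanishes; gamma is equally spaced over [0, 2 pi).  Weights are
    normalized to sum to one.
    """

    n_beta: int = 128
    n_gamma: int = 64
    name: str = "midpoint-sinbeta"
    beta: np.ndarray = field(init=False, repr=False)
    gamma: np.ndarray = field(init=False, repr=False)
    weight: np.ndarray = field(init=False, repr=False)
    _unit_phase_cache: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_beta < 2 or self.n_gamma < 2:
            raise ValueError("powder grid needs at least 2 points per angle")
        b = (np.arange(self.n_beta) + 0.5) * np.pi / self.n_beta
        g = np.arange(self.n_gamma) * 2.0 * np.pi / self.n_gamma
        bb, gg = np.meshgrid(b, g, indexing="ij")
        w = np.sin(bb)
        self.beta = bb.ravel()
        self.gamma = gg.ravel()
        self.weight = (w / w.sum()).ravel()

    def unit_phase(self, mas: MASCondition) -> np.ndarray:
        """Phase per Hz of d_eff, shape (n_orientations, n_t1). Cached."""
        key = (mas.nu_r, mas.t1_grid.tobytes())
        cached = self._unit_phase_cache.get(key)
        if cached is None:
            cached = dipolar_phase(
                1.0,
                self.beta[:, None],
                self.gamma[:, None],
                mas.t1_grid[None, :],
                mas.nu_r,
            )
            self._unit_phase_cache[key] = cached
        return cached

    def doubled(self) -> "PowderScheme":
        return PowderScheme(n_beta=2 * self.n_beta, n_gamma=2 * self.n_gamma,
                            name=self.name)


_DEFAULT_POWDER: PowderScheme | None = None


def default_powder() -> PowderScheme:
    """Module-wide default powder scheme (shared so its cache is reused)."""
    global _DEFAULT_POWDER
    if _DEFAULT_POWDER is None:
        _DEFAULT_POWDER = PowderScheme()
    return _DEFAULT_POWDER


@dataclass
class DephasingCurve:
    """A dipolar dephasing curve: normalized intensity vs t1 delay."""

    mas: MASCondition
    intensities: np.ndarray
    excitation: str = "direct"  # "cp" or "direct"
    contact_time: float | None = None
    label: str = ""
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.mas.t1_grid.shape:
            raise ValueError("intensities and t1_grid must have equal length")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.excitation not in ("cp", "direct"):
            raise ValueError("excitation must be 'cp' or 'direct'")
        if self.excitation == "cp" and self.contact_time is None:
            raise ValueError("CP excitation requires a contact_time")

    def normalized(self) -> "DephasingCurve":
        """Copy with intensities scaled so the t1 = 0 point equals 1."""
        i0 = self.intensities[0]
        if i0 == 0:
            raise ValueError("cannot normalize: zero intensity at t1 = 0")
        return DephasingCurve(
            mas=self.mas,
            intensities=self.intensities / i0,
            excitation=self.excitation,
            contact_time=self.contact_time,
            label=self.label,
            noise_sd=self.noise_sd,
        )


def dipolar_phase(d_eff, beta, gamma, t1, nu_r: float):
    """Closed-form dipolar phase Phi(t1) in rad for orientation (beta, gamma).

    Integrates omega(t) from 0 to t1 analytically.  Accepts scalars or
    broadcastable arrays.  Phi(0) = 0 and Phi(tau_r) = 0 for every
    orientation.
    """
    if nu_r <= 0:
        raise ValueError("nu_r must be positive")
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 < -1e-15) or np.any(t1 > 1.0 / nu_r * (1 + 1e-12)):
        raise ValueError("t1 must lie within one rotor period")
    wr = 2.0 * np.pi * nu_r
    c1 = np.sqrt(2.0) / 2.0 * np.sin(2.0 * np.asarray(beta))
    c2 = -0.5 * np.sin(np.asarray(beta)) ** 2
    g = np.asarray(gamma)
    # integral of 2*pi*d_eff*[c1 cos(wr t + g) + c2 cos(2 wr t + 2 g)]
    return (np.asarray(d_eff) / nu_r) * (
        c1 * (np.sin(wr * t1 + g) - np.sin(g))
        + 0.5 * c2 * (np.sin(2.0 * wr * t1 + 2.0 * g) - np.sin(2.0 * g))
    )


def dephasing_curve(
    d_eff: float,
    mas: MASCondition,
    powder: PowderScheme | None = None,
    check_convergence: bool = False,
    convergence_tol: float = 1e-4,
    strict: bool = False,
) -> DephasingCurve:
    """Powder-averaged DIPSHIFT dephasing curve for one effective coupling.

    Parameters
    ----------
    d_eff:
        Effective heteronuclear coupling in Hz (already scaled by the
        order parameter and homonuclear-decoupling factor).
    mas:
        MAS frequency and t1 grid.
    powder:
        Orientation grid; the module default (128 x 64, sin-beta weights)
        if omitted.
    check_convergence:
        If true, re-evaluate on a doubled grid and compare pointwise.
        Deviations above ``convergence_tol`` warn (or raise when
        ``strict``).
    """
    if powder is None:
        powder = default_powder()
    u = powder.unit_phase(mas)
    inten = powder.weight @ np.cos(d_eff * u)
    if check_convergence:
        fine = powder.doubled()
        inten_fine = fine.weight @ np.cos(d_eff * fine.unit_phase(mas))
        err = float(np.max(np.abs(inten - inten_fine)))
        if err > convergence_tol:
            msg = f"powder average not converged: max change {err:.2e} on doubling"
            if strict:
                raise RuntimeError(msg)
            warnings.warn(msg, ConvergenceWarning, stacklevel=2)
    return DephasingCurve(mas=mas, intensities=inten)


def dephasing_depth(curve: DephasingCurve) -> float:
    """Maximum fractional intensity loss: 1 - min(I/I0) over the curve."""
    norm = curve.normalized()
    return float(1.0 - norm.intensities.min())
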