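"""Chemical-shift region classification and spectral integration.

Without site-specific assignment, residue-type-labelled spectra are
analyzed by integrating fixed ppm windows: per residue type a Calpha
window for alpha-helix, one for random coil, and an open-ended cutoff
below which intensity is attributed to beta-sheet (aggregated protein).
Secondary structure can also be assigned per cross peak from the
Calpha-Cbeta secondary-shift difference

    Delta = (Ca - Ca_rc) - (Cb - Cb_rc)

relative to random-coil reference shifts: positive Delta indicates helix,
negative indicates sheet.

Boundary convention: helix and coil windows are closed intervals checked
in descending-ppm order, and the sheet region is strictly below its
cutoff, so a shift printed exactly on a shared boundary always lands in
the higher-ppm window.  Gaps between windows classify as "unassigned" and
are never silently merged.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "RegionTable",
    "RandomCoilTable",
    "Spectrum1D",
    "Spectrum2D",
    "classify_shift",
    "classify_dca_dcb",
    "integrate_region_1d",
    "integrate_crosspeaks_2d",
    "class_fractions",
    "default_region_table",
    "default_random_coil_table",
]

CLASSES = ("helix", "coil", "sheet")

#: Default secondary-shift threshold (ppm) for the Delta(Ca)-Delta(Cb) rule.
DEFAULT_DELTA_THRESHOLD = 1.4


@dataclass(frozen=True)
class RegionTable:
    """Per-residue ppm windows mapping Calpha shift to secondary structure.

    ``windows[residue]`` maps "helix" and "coil" to (lo, hi) ppm pairs and
    "sheet" to a scalar upper cutoff (open-ended below).
    """

    windows: dict

    def __post_init__(self) -> None:
        for residue, spec in self.windows.items():
            helix = spec.get("helix")
            coil = spec.get("coil")
            sheet = spec.get("sheet")
            if helix is None or coil is None or sheet is None:
                raise ValueError(f"{residue}: helix, coil and sheet required")
            for name, win in (("helix", helix), ("coil", coil)):
                if win[0] >= win[1]:
                    raise ValueError(f"{residue}/{name}: lo must be < hi")
            if not (helix[0] >= coil[1] and coil[0] >= sheet):
                raise ValueError(
                    f"{residue}: windows must be ordered helix > coil > sheet"
                )

    def residues(self) -> list[str]:
        return list(self.windows)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RegionTable":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(windows={
            res: {
                "helix": tuple(spec["helix"]),
                "coil": tuple(spec["coil"]),
                "sheet": float(spec["sheet"]),
            }
            for res, spec in raw.items()
        })


@dataclass(frozen=True)
class RandomCoilTable:
    """Random-coil Calpha/Cbeta reference shifts per residue (ppm)."""

    shifts: dict

    def __post_init__(self) -> None:
        for residue, (ca, cb) in self.shifts.items():
            if ca <= 0 or cb <= 0:
                raise ValueError(f"{residue}: reference shifts must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RandomCoilTable":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(shifts={res: (float(v["ca"]), float(v["cb"]))
                           for res, v in raw.items()})


def _load_packaged_toml(name: str) -> dict:
    ref = resources.files("spinorder.data") / name
    with ref.open("rb") as fh:
        return tomllib.load(fh)


def default_region_table() -> RegionTable:
    """The analysis windows for Met, Arg and His shipped with the package."""
    raw = _load_packaged_toml("regions_default.toml")
    return RegionTable(windows={
        res: {
            "helix": tuple(spec["helix"]),
            "coil": tuple(spec["coil"]),
            "sheet": float(spec["sheet"]),
        }
        for res, spec in raw.items()
    })


def default_random_coil_table() -> RandomCoilTable:
    raw = _load_packaged_toml("random_coil.toml")
    return RandomCoilTable(shifts={res: (float(v["ca"]), float(v["cb"]))
                                   for res, v in raw.items()})


@dataclass
class Spectrum1D:
    """A 1-D spectrum: ppm axis (descending by NMR convention) + intensity."""

    ppm: np.ndarray
    intensity: np.ndarray
    original_order: str = field(default="descending")

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if ppm.shape != inten.shape or ppm.ndim != 1:
            raise ValueError("ppm and intensity must be equal-length 1-D arrays")
        if not np.all(np.isfinite(inten)) or not np.all(np.isfinite(ppm)):
            raise ValueError("spectrum values must be finite")
        d = np.diff(ppm)
        if np.all(d > 0):
            self.original_order = "ascending"
            ppm, inten = ppm[::-1], inten[::-1]
        elif np.all(d < 0):
            self.original_order = "descending"
        else:
            raise ValueError("ppm axis must be strictly monotone")
        self.ppm, self.intensity = ppm, inten


@dataclass
class Spectrum2D:
    """A 2-D spectrum with two ppm axes; intensity shape (len f1, len f2)."""

    ppm_f1: np.ndarray
    ppm_f2: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        f1 = np.asarray(self.ppm_f1, dtype=float)
        f2 = np.asarray(self.ppm_f2, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        if z.shape != (f1.size, f2.size):
            raise ValueError("intensity shape must be (len f1, len f2)")
        for name, ax in (("f1", f1), ("f2", f2)):
            d = np.diff(ax)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} axis must be strictly monotone")
        if not np.all(np.isfinite(z)):
            raise ValueError("intensity must be finite")
        self.ppm_f1, self.ppm_f2, self.intensity = f1, f2, z


def classify_shift(residue: str, ca_ppm: float, table: RegionTable | None = None) -> str:
    """Classify a Calpha shift into helix / coil / sheet / unassigned."""
    if table is None:
        table = default_region_table()
    if residue not in table.windows:
        raise ValueError(f"unknown residue: {residue!r}")
    spec = table.windows[residue]
    for cls in ("helix", "coil"):
        lo, hi = spec[cls]
        if lo <= ca_ppm <= hi:
            return cls
    if ca_ppm < spec["sheet"]:
        return "sheet"
    return "unassigned"


def classify_dca_dcb(
    residue: str,
    ca_ppm: float,
    cb_ppm: float,
    rc: RandomCoilTable | None = None,
    t_helix: float = DEFAULT_DELTA_THRESHOLD,
    t_sheet: float = DEFAULT_DELTA_THRESHOLD,
) -> str:
    """Classify from the Calpha-Cbeta secondary-shift difference."""
    if rc is None:
        rc = default_random_coil_table()
    if residue not in rc.shifts:
        raise ValueError(f"no random-coil reference for residue {residue!r}")
    ca_rc, cb_rc = rc.shifts[residue]
    delta = (ca_ppm - ca_rc) - (cb_ppm - cb_rc)
    if delta > t_helix:
        return "helix"
    if delta < -t_sheet:
        return "sheet"
    return "coil"


def _window_integral_1d(ppm: np.ndarray, inten: np.ndarray,
                        lo: float, hi: float) -> float:
    """Trapezoidal area over [lo, hi] on an ascending axis, with edge
    interpolation so partially covered end cells contribute correctly."""
    inside = (ppm >= lo) & (ppm <= hi)
    xs = ppm[inside]
    ys = inten[inside]
    pieces_x = [xs]
    pieces_y = [ys]
    if lo > ppm[0] and (xs.size == 0 or xs[0] > lo):
        pieces_x.insert(0, np.array([lo]))
        pieces_y.insert(0, np.array([np.interp(lo, ppm, inten)]))
    if hi < ppm[-1] and (xs.size == 0 or xs[-1] < hi):
        pieces_x.append(np.array([hi]))
        pieces_y.append(np.array([np.interp(hi, ppm, inten)]))
    x = np.concatenate(pieces_x)
    y = np.concatenate(pieces_y)
    if x.size < 2:
        raise ValueError("window covers fewer than two axis points")
    return float(np.trapezoid(y, x))


def integrate_region_1d(spec: Spectrum1D, window: tuple[float, float]) -> float:
    """Trapezoidal area of a 1-D spectrum over a ppm window.

    The sign is orientation-corrected: a positive peak yields a positive
    area regardless of axis direction.
    """
    lo, hi = min(window), max(window)
    ppm_asc = spec.ppm[::-1]
    inten_asc = spec.intensity[::-1]
    if hi < ppm_asc[0] or lo > ppm_asc[-1]:
        raise ValueError(f"window ({lo}, {hi}) does not overlap the axis")
    lo_c, hi_c = max(lo, ppm_asc[0]), min(hi, ppm_asc[-1])
    return _window_integral_1d(ppm_asc, inten_asc, lo_c, hi_c)


def _boxes_overlap(a, b) -> bool:
    (a1lo, a1hi), (a2lo, a2hi) = [(min(w), max(w)) for w in a]
    (b1lo, b1hi), (b2lo, b2hi) = [(min(w), max(w)) for w in b]
    return a1lo < b1hi and b1lo < a1hi and a2lo < b2hi and b2lo < a2hi


def integrate_crosspeaks_2d(
    spec: Spectrum2D,
    boxes: list[tuple[tuple[float, float], tuple[float, float]]],
) -> list[float]:
    """Double-trapezoid volumes of rectangular (f1 window, f2 window) boxes.

    Boxes must be pairwise disjoint — overlapping boxes would double-count
    intensity and are rejected.
    """
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if _boxes_overlap(boxes[i], boxes[j]):
                raise ValueError(f"boxes {i} and {j} overlap (double counting)")

    f1 = spec.ppm_f1
    f2 = spec.ppm_f2
    z = spec.intensity
    if f1[0] > f1[-1]:
        f1, z = f1[::-1], z[::-1, :]
    if f2[0] > f2[-1]:
        f2, z = f2[::-1], z[:, ::-1]

    volumes = []
    for (w1, w2) in boxes:
        lo1, hi1 = min(w1), max(w1)
        lo2, hi2 = min(w2), max(w2)
        if hi1 < f1[0] or lo1 > f1[-1] or hi2 < f2[0] or lo2 > f2[-1]:
            raise ValueError("box does not overlap both axes")
        m1 = (f1 >= lo1) & (f1 <= hi1)
        m2 = (f2 >= lo2) & (f2 <= hi2)
        if m1.sum() < 2 or m2.sum() < 2:
            raise ValueError("box covers fewer than two points on an axis")
        sub = z[np.ix_(m1, m2)]
        inner = np.trapezoid(sub, f2[m2], axis=1)
        volumes.append(float(np.trapezoid(inner, f1[m1])))
    return volumes


def class_fractions(values: dict) -> dict:
    """Normalize per-class areas/volumes to fractions summing to one."""
    if not values:
        raise ValueError("no class values given")
    for cls, v in values.items():
        if v < 0:
            raise ValueError(f"negative value for class {cls!r}")
    total = sum(values.values())
    if total <= 0:
        raise ValueError("all class values are zero")
    return {cls: v / total for cls, v in values.items()}
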