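"""Plain-text interchange formats.

Curves are TSV with ``# key: value`` metadata headers and columns
``t1_us`` / ``intensity``; 1-D spectra are two-column CSV/TSV
(ppm, intensity) with the same header convention; 2-D spectra are matrix
TSV whose first row and first column carry the two ppm axes.  Values are
written with 12 significant digits so write -> read round-trips are
lossless well beyond 9 digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .regions import Spectrum1D, Spectrum2D
from .simulate import DephasingCurve, MASCondition

__all__ = [
    "FormatError",
    "read_curve",
    "write_curve",
    "read_spectrum_1d",
    "write_spectrum_1d",
    "read_spectrum_2d",
    "write_spectrum_2d",
]

_FLOAT = "{:.12g}"


class FormatError(ValueError):
    """A file does not conform to the expected plain-text format."""


def _parse_headers_and_rows(path: Path, sep: str):
    meta: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            rows.append((lineno, [f.strip() for f in line.split(sep)]))
    return meta, rows


def write_curve(curve: DephasingCurve, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# mas_hz: {_FLOAT.format(curve.mas.nu_r)}",
             f"# excitation: {curve.excitation}"]
    if curve.contact_time is not None:
        lines.append(f"# contact_time_us: {_FLOAT.format(curve.contact_time * 1e6)}")
    if curve.label:
        lines.append(f"# label: {curve.label}")
    if curve.noise_sd is not None:
        lines.append(f"# noise_sd: {_FLOAT.format(curve.noise_sd)}")
    lines.append("t1_us\tintensity")
    for t, i in zip(curve.mas.t1_grid, curve.intensities):
        lines.append(f"{_FLOAT.format(t * 1e6)}\t{_FLOAT.format(i)}")
    path.write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path) -> DephasingCurve:
    path = Path(path)
    meta, rows = _parse_headers_and_rows(path, "\t")
    if "mas_hz" not in meta:
        raise FormatError(f"{path}: missing required '# mas_hz:' header")
    nu_r = float(meta["mas_hz"])
    tau_us = 1e6 / nu_r

    if not rows:
        raise FormatError(f"{path}: no data rows")
    header_lineno, header = rows[0]
    try:
        i_t = header.index("t1_us")
        i_i = header.index("intensity")
    except ValueError:
        raise FormatError(
            f"{path}:{header_lineno}: column header must contain "
            "'t1_us' and 'intensity'"
        ) from None

    t1, inten = [], []
    for lineno, fields in rows[1:]:
        if len(fields) <= max(i_t, i_i):
            raise FormatError(f"{path}:{lineno}: expected "
                              f"{max(i_t, i_i) + 1} columns")
        try:
            t = float(fields[i_t])
            v = float(fields[i_i])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from None
        if t > tau_us * (1 + 1e-9):
            raise FormatError(
                f"{path}:{lineno}: t1 = {t} us beyond the rotor period "
                f"({tau_us:.6g} us at {nu_r:.6g} Hz MAS)"
            )
        t1.append(t)
        inten.append(v)
    if len(t1) < 2:
        raise FormatError(f"{path}: need at least 2 data rows")
    if any(b <= a for a, b in zip(t1, t1[1:])):
        raise FormatError(f"{path}: t1 column must be strictly ascending")

    excitation = meta.get("excitation", "direct")
    contact = meta.get("contact_time_us")
    try:
        mas = MASCondition(nu_r=nu_r, t1_grid=np.asarray(t1) * 1e-6)
        return DephasingCurve(
            mas=mas,
            intensities=np.asarray(inten),
            excitation=excitation,
            contact_time=float(contact) * 1e-6 if contact is not None else None,
            label=meta.get("label", ""),
            noise_sd=float(meta["noise_sd"]) if "noise_sd" in meta else None,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spectrum_1d(spec: Spectrum1D, path: str | Path, sep: str = ",") -> None:
    path = Path(path)
    lines = ["# spinorder 1d spectrum", f"ppm{sep}intensity"]
    for p, i in zip(spec.ppm, spec.intensity):
        lines.append(f"{_FLOAT.format(p)}{sep}{_FLOAT.format(i)}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_1d(path: str | Path) -> Spectrum1D:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    _, rows = _parse_headers_and_rows(path, sep)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    start = 0
    if rows[0][1] and not _is_number(rows[0][1][0]):
        start = 1  # column header line
    ppm, inten = [], []
    for lineno, fields in rows[start:]:
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        try:
            ppm.append(float(fields[0]))
            inten.append(float(fields[1]))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from None
    try:
        return Spectrum1D(ppm=np.asarray(ppm), intensity=np.asarray(inten))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spectrum_2d(spec: Spectrum2D, path: str | Path) -> None:
    """Matrix TSV: first row is the f2 axis, first column the f1 axis."""
    path = Path(path)
    lines = ["# spinorder 2d spectrum (rows: f1, columns: f2)"]
    lines.append("\t".join(["ppm_f1\\f2"] +
                           [_FLOAT.format(v) for v in spec.ppm_f2]))
    for f1v, row in zip(spec.ppm_f1, spec.intensity):
        lines.append("\t".join([_FLOAT.format(f1v)] +
                               [_FLOAT.format(v) for v in row]))
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_2d(path: str | Path) -> Spectrum2D:
    path = Path(path)
    _, rows = _parse_headers_and_rows(path, "\t")
    if len(rows) < 3:
        raise FormatError(f"{path}: need an axis row and >= 2 data rows")
    first_lineno, first = rows[0]
    try:
        f2 = np.asarray([float(v) for v in first[1:]])
    except ValueError:
        raise FormatError(f"{path}:{first_lineno}: f2 axis row must be "
                          "numeric after the corner cell") from None
    f1, data = [], []
    for lineno, fields in rows[1:]:
        if len(fields) != f2.size + 1:
            raise FormatError(f"{path}:{lineno}: expected {f2.size + 1} columns")
        try:
            f1.append(float(fields[0]))
            data.append([float(v) for v in fields[1:]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from None
    try:
        return Spectrum2D(ppm_f1=np.asarray(f1), ppm_f2=f2,
                          intensity=np.asarray(data))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
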