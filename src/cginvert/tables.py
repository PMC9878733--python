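"""Reading and writing tabulated curves as plain-text tables.

Two dialects are supported, mirroring the conventions of the VOTCA /
GROMACS tabulated-potential ecosystem:

``distribution``
    two columns ``r value`` — RDFs, bond/angle distributions.
``potential``
    three columns ``r value flag`` where the flag is a single character
    (``i`` inside the sampled range, ``o`` outside, ``u`` undefined).

Comment lines start with ``#`` and are preserved on a write/read round
trip; values are written with full float precision (``repr`` round-trip
faithful).  The GROMACS export helper resamples a potential onto the
engine's fixed 0.002 nm grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .grids import Curve, RadialGrid, resample

__all__ = ["read_table", "write_table", "export_gromacs", "TableParseError"]

#: fixed grid spacing (nm) of the MD engine's tabulated potentials
GROMACS_DR = 0.002

DIALECTS = ("distribution", "potential")


class TableParseError(ValueError):
    """Parse failure, carrying the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


@dataclass
class _Parsed:
    r: np.ndarray
    v: np.ndarray
    flags: list[str]
    comments: list[str]


def _parse(path) -> _Parsed:
    rs: list[float] = []
    vs: list[float] = []
    flags: list[str] = []
    comments: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            parts = line.split()
            if len(parts) < 2:
                raise TableParseError(path, lineno, "expected at least two columns")
            try:
                r = float(parts[0])
                v = float(parts[1])
            except ValueError as exc:
                raise TableParseError(path, lineno, f"not a number: {exc}") from None
            if np.isnan(r) or np.isnan(v):
                raise TableParseError(path, lineno, "NaN value in table")
            if rs and r <= rs[-1]:
                raise TableParseError(path, lineno, "distances must increase strictly")
            rs.append(r)
            vs.append(v)
            flags.append(parts[2] if len(parts) > 2 else "i")
    if len(rs) < 4:
        raise TableParseError(path, 0, "table has fewer than 4 rows")
    return _Parsed(np.array(rs), np.array(vs), flags, comments)


def read_table(path, dialect: str = "potential", kind: str | None = None) -> Curve:
    """Read a text table into a :class:`Curve` on the grid it defines.

    The grid spacing is inferred from the (strictly uniform) distance
    column; a leading ``r = 0`` row is required for curves that include
    the origin — tables starting at ``r = dr`` are padded with a zero row
    for distributions and a copy of the first value for potentials.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown table dialect {dialect!r}")
    p = _parse(path)
    dr = np.diff(p.r)
    if np.ptp(dr) > 1e-8 * dr.mean():
        raise TableParseError(path, 0, "grid spacing is not uniform")
    step = dr.mean()
    start = int(round(p.r[0] / step))
    if abs(p.r[0] - start * step) > 1e-8 * step:
        raise TableParseError(path, 0, "grid is not aligned with r = 0")
    n = start + len(p.r)
    values = np.empty(n)
    if start > 0:
        fill = 0.0 if dialect == "distribution" else p.v[0]
        values[:start] = fill
    values[start:] = p.v
    grid = RadialGrid(n_points=n, dr=step)
    default_kind = "distribution" if dialect == "distribution" else "potential"
    curve = Curve(grid, values, kind or default_kind)
    curve.comments = p.comments  # type: ignore[attr-defined]
    return curve


def write_table(curve: Curve, path, dialect: str = "potential",
                comments: list[str] | None = None,
                flags: list[str] | None = None) -> None:
    """Write a curve as a text table; lossless at full float precision."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown table dialect {dialect!r}")
    if comments is None:
        comments = getattr(curve, "comments", [])
    r = curve.grid.r
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(c if c.startswith("#") else "# " + c)
            fh.write("\n")
        for i, (ri, vi) in enumerate(zip(r, curve.values)):
            if dialect == "potential":
                flag = flags[i] if flags else "i"
                fh.write(f"{float(ri)!r} {float(vi)!r} {flag}\n")
            else:
                fh.write(f"{float(ri)!r} {float(vi)!r}\n")


def export_gromacs(curve: Curve, path, dr: float = GROMACS_DR) -> None:
    """Resample a potential to the MD engine's fixed grid and write it."""
    n = int(np.floor(curve.grid.r[-1] / dr)) + 1
    target = RadialGrid(n_points=n, dr=dr)
    write_table(resample(curve, target, method="cubic"), path, dialect="potential")
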