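"""Radial grids, tabulated curves, stacked interaction vectors and the
radially symmetric Fourier transform.

All distances are in nm, energies in kJ/mol and temperatures in K.  A
:class:`RadialGrid` carries uniformly spaced points ``r_i = i*dr`` together
with the two indices that structure every inverse-problem calculation:
``n_cut`` (the number of grid points up to the potential cutoff) and
``n_res`` (the number of points up to which the RDF mismatch is minimised,
``n_res >= n_cut``).  The conjugate :class:`KGrid` has the spacing
``dk = pi/(n_points*dr)`` so that the discrete sine-transform pair below is
an exact round trip.

The three-dimensional Fourier transform of a radially symmetric function,

    f_hat(k) = (4*pi/k) * int_0^inf r f(r) sin(kr) dr,

and its inverse are implemented with a type-I discrete sine transform; the
``k = 0`` element uses the analytic limit ``4*pi*int r^2 f dr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import fft as _fft
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "KB",
    "RadialGrid",
    "KGrid",
    "Curve",
    "InteractionLabel",
    "interaction_labels",
    "StackedField",
    "Composition",
    "radial_ft",
    "radial_ift",
    "fourier_matrix",
    "inverse_fourier_matrix",
    "resample",
]

#: Boltzmann constant in kJ/(mol K).
KB = 0.00831446

#: Conversion from kJ/(mol nm^3) to bar.
PRESSURE_TO_BAR = 1.0e3 / 6.02214076e23 / 1.0e-27 / 1.0e5


class GridError(ValueError):
    """Raised when curves live on incompatible grids."""


@dataclass(frozen=True)
class RadialGrid:
    """Uniform real-space grid ``r_i = i*dr``, ``i = 0..n_points-1``.

    ``n_cut`` and ``n_res`` are grid-point counts (indices), not lengths:
    ``r_cut = n_cut*dr`` and ``r_res = n_res*dr``.
    """

    n_points: int
    dr: float
    n_cut: int = 0
    n_res: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("need at least 4 grid points")
        if not self.dr > 0:
            raise ValueError("grid spacing must be positive")
        if self.n_cut == 0:
            object.__setattr__(self, "n_cut", self.n_points - 1)
        if self.n_res == 0:
            # residuum range defaults to the potential range (Newton case)
            object.__setattr__(self, "n_res", self.n_cut)
        if self.n_cut < 2:
            raise ValueError("n_cut must be at least 2")
        if self.n_res < self.n_cut:
            raise ValueError("n_res must be >= n_cut")
        if self.n_res > self.n_points - 1:
            raise ValueError("n_res exceeds the grid")

    @classmethod
    def from_lengths(cls, dr: float, r_max: float, r_cut: float | None = None,
                     r_res: float | None = None) -> "RadialGrid":
        """Build a grid from physical lengths, rounding to grid points."""
        n = int(round(r_max / dr))
        n_cut = int(round((r_cut if r_cut is not None else r_max) / dr))
        n_cut = min(n_cut, n - 1)
        n_res = int(round(r_res / dr)) if r_res is not None else n_cut
        n_res = min(max(n_res, n_cut), n - 1)
        return cls(n_points=n, dr=dr, n_cut=n_cut, n_res=n_res)

    @property
    def r(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dr

    @property
    def midpoints(self) -> np.ndarray:
        """Half-shifted points ``r_i' = (i + 1/2)*dr``."""
        return (np.arange(self.n_points - 1) + 0.5) * self.dr

    @property
    def r_cut(self) -> float:
        return self.n_cut * self.dr

    @property
    def r_res(self) -> float:
        return self.n_res * self.dr

    def k_grid(self) -> "KGrid":
        return KGrid(n_points=self.n_points, dk=np.pi / (self.n_points * self.dr))

    def with_cut(self, n_cut: int | None = None, n_res: int | None = None) -> "RadialGrid":
        return replace(self, n_cut=n_cut or self.n_cut, n_res=n_res or self.n_res)


@dataclass(frozen=True)
class KGrid:
    """Wave-vector grid conjugate to a :class:`RadialGrid`."""

    n_points: int
    dk: float

    @property
    def k(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dk


CURVE_KINDS = ("rdf", "potential", "correlation", "distribution")


@dataclass
class Curve:
    """Tabulated radial function on a :class:`RadialGrid` or :class:`KGrid`."""

    grid: RadialGrid | KGrid
    values: np.ndarray
    kind: str = "correlation"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise GridError(
                f"curve has {self.values.size} values for a grid of "
                f"{self.grid.n_points} points"
            )
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")
        if self.kind == "rdf" and np.any(self.values < 0):
            raise ValueError("an RDF must be nonnegative everywhere")

    def copy(self) -> "Curve":
        return Curve(self.grid, self.values.copy(), self.kind)


@dataclass(frozen=True, order=True)
class InteractionLabel:
    """Unordered bead-type pair; ``(a, b)`` and ``(b, a)`` are identical."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.b < self.a:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.a}-{self.b}"

    @property
    def is_like(self) -> bool:
        return self.a == self.b


def interaction_labels(types: Iterable[str]) -> list[InteractionLabel]:
    """All ``n_t*(n_t+1)/2`` unordered pairs, lexicographic, AA < AB < BB."""
    ts = sorted(set(types))
    return [InteractionLabel(a, b) for i, a in enumerate(ts) for b in ts[i:]]


class StackedField:
    """Ordered collection of per-interaction curves, flattenable to one vector.

    The flattening order is lexicographic in the sorted type names of each
    label (AA before AB before BB); within one interaction the curve values
    appear in grid order.
    """

    def __init__(self, labels: Sequence[InteractionLabel], curves: Sequence[Curve]):
        if len(labels) != len(curves):
            raise ValueError("one curve per interaction label required")
        idx = sorted(range(len(labels)), key=lambda i: (labels[i].a, labels[i].b))
        self.labels: tuple[InteractionLabel, ...] = tuple(labels[i] for i in idx)
        self.curves: tuple[Curve, ...] = tuple(curves[i] for i in idx)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate interaction labels")
        g0 = self.curves[0].grid
        for c in self.curves:
            if c.grid.n_points != g0.n_points:
                raise GridError("all curves in a stack must share a grid")

    @property
    def grid(self):
        return self.curves[0].grid

    @property
    def n_interactions(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: InteractionLabel | str) -> Curve:
        if isinstance(label, str):
            a, b = label.split("-")
            label = InteractionLabel(a, b)
        for l, c in zip(self.labels, self.curves):
            if l == label:
                return c
        raise KeyError(str(label))

    def flatten(self) -> np.ndarray:
        return np.concatenate([c.values for c in self.curves])

    @classmethod
    def unflatten(cls, vector: np.ndarray, labels: Sequence[InteractionLabel],
                  grid, kind: str = "correlation") -> "StackedField":
        vector = np.asarray(vector, dtype=float)
        n = grid.n_points
        if vector.size != n * len(labels):
            raise ValueError("vector length does not match labels and grid")
        curves = [Curve(grid, vector[i * n:(i + 1) * n], kind)
                  for i in range(len(labels))]
        return cls(list(labels), curves)

    def map(self, fn, kind: str | None = None) -> "StackedField":
        """Apply ``fn`` to every curve's values, returning a new stack."""
        return StackedField(
            list(self.labels),
            [Curve(c.grid, fn(c.values), kind or c.kind) for c in self.curves],
        )


@dataclass(frozen=True)
class Composition:
    """Bead counts, box volume (nm^3) and temperature (K) of the system."""

    counts: dict[str, int] = field(default_factory=dict)
    volume: float = 0.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("at least one bead type required")
        if any(n <= 0 for n in self.counts.values()):
            raise ValueError("bead counts must be positive")
        if not (self.volume > 0 and self.temperature > 0):
            raise ValueError("volume and temperature must be positive")

    @property
    def types(self) -> list[str]:
        return sorted(self.counts)

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT

    def density(self, t: str) -> float:
        """Bead number density rho_alpha = N_alpha / V in nm^-3."""
        return self.counts[t] / self.volume

    @property
    def total_density(self) -> float:
        return sum(self.counts.values()) / self.volume


# ---------------------------------------------------------------------------
# radially symmetric Fourier transforms


def _check_radial(curve: Curve) -> RadialGrid:
    if not isinstance(curve.grid, RadialGrid):
        raise GridError("expected a curve on a real-space grid")
    return curve.grid


def radial_ft(curve: Curve, grid: RadialGrid | None = None) -> Curve:
    """3D Fourier transform of a radially symmetric function.

    Returns ``f_hat(k_j)`` on the conjugate :class:`KGrid`; ``k = 0`` holds
    the analytic limit ``4*pi*sum r^2 f dr``.
    """
    g = _check_radial(curve)
    if grid is not None and grid != g:
        raise GridError("curve does not live on the supplied grid")
    r = g.r
    f = curve.values
    kg = g.k_grid()
    out = np.empty(g.n_points)
    # dst type 1: y_j = 2 sum_{i=1}^{n-1} x_i sin(pi i j / n)
    s = _fft.dst(r[1:] * f[1:], type=1)
    out[1:] = 2.0 * np.pi * g.dr * s / kg.k[1:]
    out[0] = 4.0 * np.pi * g.dr * np.sum(r * r * f)
    return Curve(kg, out, curve.kind)


def radial_ift(curve: Curve, grid: RadialGrid | None = None) -> Curve:
    """Inverse of :func:`radial_ft` on the paired grids."""
    if not isinstance(curve.grid, KGrid):
        raise GridError("expected a curve on a wave-vector grid")
    kg = curve.grid
    if grid is None:
        grid = RadialGrid(n_points=kg.n_points, dr=np.pi / (kg.n_points * kg.dk))
    elif abs(grid.dr * kg.dk * kg.n_points - np.pi) > 1e-12 * np.pi:
        raise GridError("real and wave-vector grids are not conjugate")
    k = kg.k
    fh = curve.values
    out = np.empty(kg.n_points)
    s = _fft.dst(k[1:] * fh[1:], type=1)
    r = grid.r
    out[1:] = kg.dk * s / (4.0 * np.pi ** 2 * r[1:])
    out[0] = kg.dk * np.sum(k * k * fh) / (2.0 * np.pi ** 2)
    return Curve(grid, out, curve.kind)


def fourier_matrix(grid: RadialGrid) -> np.ndarray:
    """Dense forward-transform matrix over the interior points ``i = 1..n-1``.

    ``(F f)_j = f_hat(k_j)`` for ``j = 1..n-1``; used to conjugate per-k
    derivative operators into real space.
    """
    r = grid.r[1:]
    k = grid.k_grid().k[1:]
    return 4.0 * np.pi * grid.dr * r[None, :] * np.sin(np.outer(k, r)) / k[:, None]


def inverse_fourier_matrix(grid: RadialGrid) -> np.ndarray:
    """Exact inverse of :func:`fourier_matrix` (DST orthogonality)."""
    r = grid.r[1:]
    k = grid.k_grid().k[1:]
    dk = grid.k_grid().dk
    return dk * k[None, :] * np.sin(np.outer(r, k)) / (2.0 * np.pi ** 2 * r[:, None])


# ---------------------------------------------------------------------------
# resampling


def resample(curve: Curve, new_grid: RadialGrid, method: str = "cubic",
             allow_extrapolation: bool = False) -> Curve:
    """Interpolate a curve onto a new grid (cubic by default).

    Exact at shared nodes; raises unless the new grid lies within the
    source support or extrapolation is explicitly allowed.
    """
    g = _check_radial(curve)
    r_old, r_new = g.r, new_grid.r
    if not allow_extrapolation and r_new[-1] > r_old[-1] + 1e-12 * g.dr:
        raise GridError(
            "target grid extends beyond the source support; pass "
            "allow_extrapolation=True to override"
        )
    if method == "cubic":
        interp = CubicSpline(r_old, curve.values, extrapolate=True)
        vals = interp(r_new)
    elif method == "linear":
        interp = interp1d(r_old, curve.values, kind="linear",
                          fill_value="extrapolate")
        vals = interp(r_new)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    if curve.kind == "rdf":
        vals = np.clip(vals, 0.0, None)
    return Curve(new_grid, vals, curve.kind)
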