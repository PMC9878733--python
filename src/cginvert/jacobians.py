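"""Jacobians of the RDF with respect to the pair potential.

Three routes are implemented:

* ``jacobian_hnc`` — differentiate the HNC closure.  The closure inverts
  to ``u = kT (h - c - ln g)``, so the *inverse* Jacobian has elements

      (du/dg)_{Ii,Jj} = kT * [ delta_IJ delta_ij (1 - 1/gbar_i)
                               - (dc/dh)_{Ii,Jj} ],

  where the diagonal uses the average ``gbar = (g_tgt + g_k)/2`` of the
  target and current RDF — the "a-Newton" stabilisation that keeps the
  update bounded in the RDF onset region.

* ``jacobian_imc`` — inverse Monte Carlo.  The Jacobian of the pair-count
  vector ``S`` with respect to ``u`` follows exactly from particle-number
  cross-correlations, ``A = -beta (<S S> - <S><S>)``; dividing each row
  by the ``S <-> g`` normalisation ``4 pi r_i^2 dr N_a N_b / ((1+d_ab) V)``
  converts it to ``dg/du``.  The statistics must come from an NVT-like
  ensemble (a barostat rescales pair distances and biases the
  correlations).

* ``jacobian_lowdensity_diag`` — the diagonal ``dg/du = -gbar/kT`` of the
  zero-density limit ``g = exp(-u/kT)``; this is the Newton scheme that
  is numerically close to iterative Boltzmann inversion (IBI).

``improve_imc`` interpolates row-wise between the sampled IMC Jacobian
and the diagonal low-density one below a pair of RDF thresholds, with a
square-root weight that compensates the exponential growth of the RDF
through its onset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .grids import Composition, Curve, InteractionLabel, RadialGrid, StackedField

__all__ = [
    "StackIndex",
    "OnsetPolicy",
    "ImcStats",
    "flatten_bins",
    "unflatten_bins",
    "jacobian_hnc",
    "jacobian_lowdensity_diag",
    "imc_stats",
    "jacobian_imc",
    "improve_imc",
    "ibi_update",
    "pair_count_factors",
    "save_imc_stats",
    "load_imc_stats",
]


@dataclass(frozen=True)
class StackIndex:
    """Flat indexing over (interaction, interior grid point).

    Grid point ``i`` runs over ``1 .. n_bins`` (the ``r = 0`` bin is
    excluded throughout: RDFs vanish there and the bin volume is zero).
    """

    labels: tuple[InteractionLabel, ...]
    n_bins: int

    @property
    def size(self) -> int:
        return len(self.labels) * self.n_bins

    def block(self, label: InteractionLabel) -> slice:
        I = self.labels.index(label)
        return slice(I * self.n_bins, (I + 1) * self.n_bins)

    def flat(self, label: InteractionLabel, i: int) -> int:
        if not 1 <= i <= self.n_bins:
            raise IndexError(f"grid point {i} outside 1..{self.n_bins}")
        return self.labels.index(label) * self.n_bins + (i - 1)


def flatten_bins(stack: StackedField, index: StackIndex) -> np.ndarray:
    """Stack curve values on interior bins ``1..n_bins`` into one vector."""
    if tuple(stack.labels) != index.labels:
        raise ValueError("stack labels do not match the index")
    return np.concatenate([c.values[1:index.n_bins + 1] for c in stack.curves])


def unflatten_bins(vec: np.ndarray, index: StackIndex, grid: RadialGrid,
                   kind: str = "potential") -> StackedField:
    """Inverse of :func:`flatten_bins`; bins outside ``1..n_bins`` are zero."""
    m = index.n_bins
    curves = []
    for I, label in enumerate(index.labels):
        v = np.zeros(grid.n_points)
        v[1:m + 1] = vec[I * m:(I + 1) * m]
        curves.append(Curve(grid, v, kind))
    return StackedField(list(index.labels), curves)


def _gbar(g_tgt: StackedField, g_k: StackedField, index: StackIndex) -> np.ndarray:
    gt = flatten_bins(g_tgt, index)
    gk = flatten_bins(g_k, index)
    gbar = 0.5 * (gt + gk)
    if np.any(gbar <= 0):
        raise ValueError(
            "the averaged RDF vanishes inside the update range; "
            "extrapolate the RDF onset first"
        )
    return gbar


def jacobian_hnc(g_tgt: StackedField, g_k: StackedField, dcdh_mat: np.ndarray,
                 kT: float, index: StackIndex) -> np.ndarray:
    """HNC Jacobian in inverse form, ``du/dg``, on the square index space.

    ``dcdh_mat`` is the real-space derivative matrix from
    :func:`cginvert.rism.dcdh_real`, truncated to ``index.n_bins`` bins.
    Newton uses the result as-is; Gauss-Newton inverts it.
    """
    n = index.size
    if dcdh_mat.shape != (n, n):
        raise ValueError(
            f"dc/dh matrix has shape {dcdh_mat.shape}, expected {(n, n)}"
        )
    gbar = _gbar(g_tgt, g_k, index)
    Jinv = -kT * dcdh_mat
    idx = np.arange(n)
    Jinv[idx, idx] += kT * (1.0 - 1.0 / gbar)
    return Jinv


def jacobian_lowdensity_diag(g_tgt: StackedField, g_k: StackedField, kT: float,
                             index: StackIndex) -> np.ndarray:
    """Diagonal low-density Jacobian ``dg/du = -gbar/kT`` (a-Newton form)."""
    return np.diag(-_gbar(g_tgt, g_k, index) / kT)


@dataclass(frozen=True)
class OnsetPolicy:
    """Thresholds of the onset stabilisation of the IMC Jacobian.

    Below ``t1`` a row is replaced by the diagonal low-density row, above
    ``t2`` it is untouched, in between the rows are blended with the
    square-root weight ``w = sqrt((g - t1)/(t2 - t1))``.  The value
    compared against the thresholds is ``min(g_tgt, g_k)`` per element —
    the conservative choice that stabilises whenever either curve is
    still in its onset (configurable via ``reference``).
    """

    t1: float = 0.001
    t2: float = 0.1
    reference: str = "min"  # one of min, target, current, mean

    def __post_init__(self) -> None:
        if not 0 < self.t1 < self.t2:
            raise ValueError("onset thresholds must satisfy 0 < t1 < t2")
        if self.reference not in ("min", "target", "current", "mean"):
            raise ValueError(f"unknown onset reference {self.reference!r}")

    def reference_rdf(self, g_tgt: np.ndarray, g_k: np.ndarray) -> np.ndarray:
        if self.reference == "min":
            return np.minimum(g_tgt, g_k)
        if self.reference == "target":
            return g_tgt
        if self.reference == "current":
            return g_k
        return 0.5 * (g_tgt + g_k)


@dataclass
class ImcStats:
    """Accumulated pair-count statistics for the IMC Jacobian.

    ``mean`` is ``<S>`` over the flat (interaction, bin) index; ``second``
    is the raw second-moment matrix ``<S_i S_j>``.
    """

    index: StackIndex
    mean: np.ndarray
    second: np.ndarray
    n_frames: int
    ensemble: str = "nvt"

    @property
    def covariance(self) -> np.ndarray:
        return self.second - np.outer(self.mean, self.mean)

    def jacobian_a(self, kT: float) -> np.ndarray:
        """The S/u Jacobian ``A = -beta * cov(S, S)``."""
        return -self.covariance / kT


def imc_stats(samples: np.ndarray, index: StackIndex,
              ensemble: str = "nvt") -> ImcStats:
    """Means and second moments of per-frame pair-count vectors.

    The t-IMC variant is the same computation applied to samples from the
    reference (target) ensemble.  Anything but an NVT-like ensemble is
    rejected: constant-pressure sampling biases the count correlations.
    """
    if ensemble.lower().replace("-", "") not in ("nvt", "canonical"):
        raise ValueError(
            f"IMC statistics require the NVT ensemble, got {ensemble!r}"
        )
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] != index.size:
        raise ValueError(
            f"sample dimension {samples.shape[1]} does not match index size "
            f"{index.size}"
        )
    mean = samples.mean(axis=0)
    second = samples.T @ samples / samples.shape[0]
    second = 0.5 * (second + second.T)
    return ImcStats(index, mean, second, samples.shape[0], "nvt")


def pair_count_factors(composition: Composition, grid: RadialGrid,
                       index: StackIndex) -> np.ndarray:
    """Per-row conversion ``S = factor * g``:
    ``factor_Ii = 4 pi r_i^2 dr N_a N_b / ((1 + d_ab) V)``."""
    r = grid.r
    out = np.empty(index.size)
    for I, label in enumerate(index.labels):
        na = composition.counts[label.a]
        nb = composition.counts[label.b]
        pref = na * nb / ((1.0 + (label.a == label.b)) * composition.volume)
        ri = r[1:index.n_bins + 1]
        out[I * index.n_bins:(I + 1) * index.n_bins] = (
            4.0 * np.pi * ri ** 2 * grid.dr * pref
        )
    return out


def jacobian_imc(stats: ImcStats, composition: Composition,
                 grid: RadialGrid) -> np.ndarray:
    """IMC Jacobian ``dg/du`` from pair-count statistics."""
    A = stats.jacobian_a(composition.kT)
    factors = pair_count_factors(composition, grid, stats.index)
    return A / factors[:, None]


def improve_imc(J: np.ndarray, g_tgt: StackedField, g_k: StackedField,
                policy: OnsetPolicy, kT: float, index: StackIndex) -> np.ndarray:
    """Onset stabilisation: blend Jacobian rows toward the diagonal form.

    Rows whose reference RDF value is below ``t1`` become the pure
    ``-gbar/kT`` diagonal row; rows at or above ``t2`` are returned
    bitwise unchanged; in between the full row (including off-diagonal
    elements) is damped by ``w = sqrt((g - t1)/(t2 - t1))`` and the
    diagonal row mixed in with weight ``1 - w``.
    """
    gt = flatten_bins(g_tgt, index)
    gk = flatten_bins(g_k, index)
    gref = policy.reference_rdf(gt, gk)
    gbar = 0.5 * (gt + gk)
    out = J.copy()
    n = index.size
    diag_val = -gbar / kT
    for row in range(n):
        if gref[row] >= policy.t2:
            continue
        if gref[row] <= policy.t1:
            out[row, :] = 0.0
            out[row, row] = diag_val[row]
        else:
            w = np.sqrt((gref[row] - policy.t1) / (policy.t2 - policy.t1))
            out[row, :] = w * J[row, :]
            out[row, row] += (1.0 - w) * diag_val[row]
    return out


def ibi_update(g_tgt: StackedField, g_k: StackedField, kT: float) -> StackedField:
    """Iterative Boltzmann inversion step ``du = kT ln(g_k / g_tgt)``.

    Applies pointwise wherever both RDFs are positive; also valid for
    bonded distributions.  Nonpositive values inside the sampled support
    (extrapolate the onset first) raise.
    """
    curves = []
    for label in g_tgt.labels:
        gt = g_tgt[label].values
        gk = g_k[label].values
        if np.any(gt[1:] <= 0) or np.any(gk[1:] <= 0):
            raise ValueError(
                f"nonpositive RDF values for {label}; extrapolate the onset "
                "before an IBI update"
            )
        du = np.zeros_like(gt)
        du[1:] = kT * np.log(gk[1:] / gt[1:])
        du[0] = du[1] if (gt[0] <= 0 or gk[0] <= 0) else kT * np.log(gk[0] / gt[0])
        curves.append(Curve(g_tgt[label].grid, du, "potential"))
    return StackedField(list(g_tgt.labels), curves)


# ---------------------------------------------------------------------------
# serialization of IMC statistics (compute once, reuse for t-IMC)


def save_imc_stats(stats: ImcStats, path) -> None:
    """Write statistics as a text file: header, mean row, dense moments."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cginvert IMC statistics\n")
        fh.write("# interactions: "
                 + " ".join(str(l) for l in stats.index.labels) + "\n")
        fh.write(f"# n_bins: {stats.index.n_bins}\n")
        fh.write(f"# n_frames: {stats.n_frames}\n")
        fh.write(f"# ensemble: {stats.ensemble}\n")
        np.savetxt(fh, stats.mean[None, :])
        np.savetxt(fh, stats.second)


def load_imc_stats(path) -> ImcStats:
    labels: list[InteractionLabel] = []
    n_bins = n_frames = 0
    ensemble = "nvt"
    rows: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("interactions:"):
                    labels = [InteractionLabel(*p.split("-"))
                              for p in body.split(":", 1)[1].split()]
                elif body.startswith("n_bins:"):
                    n_bins = int(body.split(":", 1)[1])
                elif body.startswith("n_frames:"):
                    n_frames = int(body.split(":", 1)[1])
                elif body.startswith("ensemble:"):
                    ensemble = body.split(":", 1)[1].strip()
                continue
            rows.append(line)
    data = np.loadtxt(io.StringIO("\n".join(rows)))
    index = StackIndex(tuple(labels), n_bins)
    return ImcStats(index, data[0], data[1:], n_frames, ensemble)
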