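"""RDF onset extrapolation and convergence/noise metrics.

Atomistic RDFs vanish at short distance (Pauli repulsion) and the onset
where they rise from zero is poorly sampled: values jitter over orders
of magnitude and below some threshold are exactly zero.  Inverting such
data produces noisy, unstable repulsive potentials.  The cure used here
assumes the onset follows ``g = exp(-u/kT)`` with an exponentially
decaying repulsive potential: take ``-log g``, fit ``f = a exp(-b r) + c``
in the well-sampled window, and replace the poorly sampled values by
``exp(-f)``.

Metrics:

* ``chi_u`` — target-RDF-weighted squared potential difference, summed
  over interactions; measures convergence toward a known reference
  potential only where the structure is actually sampled.
* ``chi_g`` — collective squared RDF mismatch over all interactions.
* ``noise_sigma`` — per-interaction cubic fit of the last 20 grid points
  left of the cutoff; the root of the summed squared residuals, averaged
  over interactions, is an estimate of the sampling noise amplitude and
  scales as (number of frames)**-1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .grids import Curve, RadialGrid, StackedField

__all__ = [
    "OnsetFitWindow",
    "extrapolate_onset",
    "chi_u",
    "chi_g",
    "noise_sigma",
]


@dataclass(frozen=True)
class OnsetFitWindow:
    """RDF-value window delimiting the onset fit region.

    The fit uses points with ``lower <= g <= upper``; points below
    ``replace_below`` (defaults to ``lower``) and to the left of the fit
    window are replaced by the extrapolation.
    """

    lower: float = 0.001
    upper: float = 0.1
    replace_below: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper <= 1:
            raise ValueError("need 0 < lower < upper <= 1")

    @property
    def threshold(self) -> float:
        return self.replace_below if self.replace_below is not None else self.lower


def _exp_decay(x, a, b, c):
    return a * np.exp(-b * x) + c


def _fit_neglog(r: np.ndarray, y: np.ndarray):
    """Fit y = a*exp(-b r) + c; fall back to a log-linear fit (c = 0)."""
    # slope-based initial guesses from the window endpoints
    c0 = max(min(y) * 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(np.clip(y - c0, 1e-12, None))
    b0, loga0 = np.polyfit(r, z, 1)
    b0 = max(-b0, 1e-6)
    a0 = np.exp(loga0)
    try:
        popt, _ = curve_fit(_exp_decay, r, y, p0=(a0, b0, c0), maxfev=10000)
        if popt[0] <= 0 or popt[1] <= 0:
            raise RuntimeError("unphysical fit")
        return lambda x: _exp_decay(x, *popt)
    except (RuntimeError, ValueError):
        # documented fallback: straight line through log(-log g), c = 0
        slope, intercept = np.polyfit(r, np.log(np.clip(y, 1e-12, None)), 1)
        return lambda x: np.exp(intercept + slope * x)


def extrapolate_onset(g: Curve, window: OnsetFitWindow | None = None) -> Curve:
    """Extrapolate the RDF onset below the sampling threshold.

    Values below ``window.threshold`` (and left of the fit window) become
    ``exp(-f(r))`` with ``f`` the fitted decay of ``-log g``; everything
    above the window is untouched, so the operation is idempotent up to
    the fit tolerance and never reduces the number of positive bins.
    """
    if window is None:
        window = OnsetFitWindow()
    grid: RadialGrid = g.grid
    vals = g.values
    # onset fit region: contiguous run of window values at the first rise
    above = np.nonzero(vals >= window.upper)[0]
    if above.size == 0:
        raise ValueError("RDF never reaches the upper fit threshold")
    first_high = above[0]
    if not np.any(vals[:first_high + 1] < window.threshold):
        # nothing below the sampling threshold: no onset to repair
        return g.copy()
    in_window = np.nonzero(
        (vals[:first_high + 1] >= window.lower)
        & (vals[:first_high + 1] <= window.upper)
    )[0]
    if in_window.size < 4:
        raise ValueError(
            "fewer than 4 RDF points inside the onset fit window; widen the "
            "thresholds"
        )
    r_fit = grid.r[in_window]
    y_fit = -np.log(vals[in_window])
    f = _fit_neglog(r_fit, y_fit)
    out = vals.copy()
    replace = np.nonzero(
        (np.arange(grid.n_points) < in_window[0]) & (vals < window.threshold)
    )[0]
    # floor keeps the replaced region strictly positive even where the
    # fitted exponent underflows (deep core, r -> 0)
    out[replace] = np.maximum(
        np.exp(np.maximum(-np.asarray(f(grid.r[replace]), dtype=float), -570.0)),
        1e-250,
    )
    return Curve(grid, np.clip(out, 0.0, None), "rdf")


def extrapolate_all(g: StackedField, window: OnsetFitWindow | None = None) -> StackedField:
    """Apply :func:`extrapolate_onset` to every interaction of a stack."""
    return StackedField(
        list(g.labels), [extrapolate_onset(c, window) for c in g.curves]
    )


def _check_same_grid(a: StackedField, b: StackedField) -> None:
    if a.grid.n_points != b.grid.n_points or abs(a.grid.dr - b.grid.dr) > 1e-12:
        raise ValueError("stacked fields live on different grids")


def chi_u(u: StackedField, u_ref: StackedField, g_tgt: StackedField,
          n_max: int | None = None) -> float:
    """Target-weighted potential mismatch
    ``sum_I sum_i g_tgt(r_i) (u - u_ref)^2 dr``  [(kJ/mol)^2 nm]."""
    _check_same_grid(u, u_ref)
    _check_same_grid(u, g_tgt)
    n = n_max if n_max is not None else u.grid.n_points
    total = 0.0
    for label in u.labels:
        du = u[label].values[:n] - u_ref[label].values[:n]
        total += float(np.sum(g_tgt[label].values[:n] * du ** 2)) * u.grid.dr
    return total


def chi_g(g: StackedField, g_tgt: StackedField, n_max: int | None = None) -> float:
    """Collective RDF mismatch ``sum_I sum_i (g - g_tgt)^2 dr``  [nm]."""
    _check_same_grid(g, g_tgt)
    n = n_max if n_max is not None else min(g.grid.n_points, g.grid.n_res + 1)
    total = 0.0
    for label in g.labels:
        dg = g[label].values[:n] - g_tgt[label].values[:n]
        total += float(np.sum(dg ** 2)) * g.grid.dr
    return total


def noise_sigma(curves: StackedField, n_cut: int | None = None,
                n_fit: int = 20) -> float:
    """Noise estimate from a cubic fit of the last points before the cutoff.

    For each interaction the ``n_fit`` grid points immediately left of
    ``n_cut`` are fitted with a third-degree polynomial; the square root
    of the summed squared residuals is averaged over interactions.
    """
    grid = curves.grid
    nc = n_cut if n_cut is not None else grid.n_cut
    if nc < n_fit:
        raise ValueError(f"need at least {n_fit} grid points before the cutoff")
    sl = slice(nc - n_fit, nc)
    r = grid.r[sl]
    total = 0.0
    for c in curves.curves:
        y = c.values[sl]
        coeff = np.polyfit(r, y, 3)
        resid = y - np.polyval(coeff, r)
        total += float(np.sqrt(np.sum(resid ** 2)))
    return total / curves.n_interactions
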