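"""Newton and constrained Gauss-Newton potential updates, and the
thermodynamic property evaluators used to build constraint rows.

Sign conventions (fixed repository-wide): the residual is
``r = g_tgt - g_k`` and an update solves ``J du ~ r`` in the (weighted)
least-squares sense, so that the linearised next RDF
``g_{k+1} = g_k + J du`` approaches the target.  Constraint rows are
written ``K du = d`` with ``d = phi_k - phi_tgt`` and ``K`` the negative
derivative of the property, so ``d = 0`` exactly when the property is on
target.

Constrained least squares is solved by direct elimination (a null-space
method): a QR factorisation of ``K^T`` splits ``du`` into a particular
solution of the constraints plus a free component minimised in the
null space of ``K``.

Properties (pressure via the discrete virial with midpoint forces, the
Kirkwood-Buff integral and the intermolecular potential energy per bead)
are all linear in ``u`` at fixed ``g``, so their ``u``-derivative rows
are exact; the ``g``-dependence of pressure and energy is neglected in
the constraint rows, which is accurate once RDF changes per iteration
are small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import qr, lstsq

from .grids import (
    Composition,
    Curve,
    InteractionLabel,
    RadialGrid,
    StackedField,
    PRESSURE_TO_BAR,
)
from .jacobians import StackIndex, flatten_bins

__all__ = [
    "ConstraintRow",
    "Selection",
    "ThermoTargets",
    "default_weights",
    "newton_step",
    "gauss_newton_step",
    "selective_reduce",
    "virial_pressure",
    "kirkwood_buff",
    "intermolecular_pe",
    "pressure_constraint",
    "kbi_constraint",
    "pe_constraint",
]

# relative singular-value cutoff for rank-deficient least squares
RCOND = 1e-10


@dataclass
class ConstraintRow:
    """One linear constraint ``coeffs . du = rhs`` on the potential update."""

    coeffs: np.ndarray
    rhs: float
    label: str

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not (np.all(np.isfinite(self.coeffs)) and np.isfinite(self.rhs)):
            raise ValueError(f"constraint {self.label!r} has non-finite entries")


@dataclass(frozen=True)
class Selection:
    """Which potentials to update and which target RDFs to match."""

    update: frozenset[InteractionLabel]
    target: frozenset[InteractionLabel]

    def __post_init__(self) -> None:
        if not self.update or not self.target:
            raise ValueError("selection must name at least one potential and "
                             "one target RDF")

    @classmethod
    def all(cls, labels: Sequence[InteractionLabel]) -> "Selection":
        s = frozenset(labels)
        return cls(update=s, target=s)


@dataclass(frozen=True)
class ThermoTargets:
    """Optional thermodynamic targets for constrained updates."""

    pressure: float | None = None            # bar
    pe: float | None = None                  # kJ/mol per bead
    kbi: dict[InteractionLabel, float] | None = None  # nm^3


def default_weights(g_tgt: StackedField, index: StackIndex) -> np.ndarray:
    """The default Gauss-Newton row weights ``r^2 / (g_tgt + 1e-30)``.

    The numerator emphasises the RDF tail (prevents jumps in the
    potential at the cutoff); the denominator emphasises the onset, whose
    mismatch otherwise destabilises the repulsive potential.
    """
    gt = flatten_bins(g_tgt, index)
    r = g_tgt.grid.r[1:index.n_bins + 1]
    r2 = np.tile(r ** 2, len(index.labels))
    return r2 / (gt + 1e-30)


def newton_step(J_inv: np.ndarray, residual: np.ndarray) -> np.ndarray:
    """Square Newton update ``du = J_inv (g_tgt - g_k)``."""
    J_inv = np.asarray(J_inv)
    residual = np.asarray(residual)
    if J_inv.shape != (residual.size, residual.size):
        raise ValueError(
            f"inverse Jacobian {J_inv.shape} does not match residual "
            f"of size {residual.size}"
        )
    return J_inv @ residual


def gauss_newton_step(J: np.ndarray, residual: np.ndarray,
                      weights: np.ndarray | None = None,
                      constraints: Sequence[ConstraintRow] = (),
                      scale: float = 1.0,
                      rcond: float = RCOND) -> np.ndarray:
    """Weighted, linearly constrained Gauss-Newton update.

    Minimises ``|| W (J du - residual) ||_2`` subject to ``K du = d``
    via direct elimination, then multiplies the result by ``scale``
    (1.0 by default; 0.67 damps overshooting updates).  Rank-deficient
    unconstrained directions take the least-norm solution with a
    relative singular-value cutoff.
    """
    J = np.asarray(J, dtype=float)
    residual = np.asarray(residual, dtype=float)
    n_rows, n_cols = J.shape
    if residual.size != n_rows:
        raise ValueError("residual length does not match Jacobian rows")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.size != n_rows or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be nonnegative, finite, one per row")
        A = w[:, None] * J
        b = w * residual
    else:
        A = J
        b = residual
    if not constraints:
        du = lstsq(A, b, cond=rcond, lapack_driver="gelsd")[0]
        return scale * du
    K = np.vstack([c.coeffs for c in constraints])
    d = np.array([c.rhs for c in constraints])
    if K.shape[1] != n_cols:
        raise ValueError("constraint coefficients do not match Jacobian columns")
    m = K.shape[0]
    Q, R = qr(K.T, mode="full")  # K^T = Q R, Q (n_cols x n_cols)
    R1 = R[:m, :]
    svals = np.abs(np.diag(R1))
    if svals.min() <= rcond * max(svals.max(), 1.0):
        bad = [constraints[i].label for i in range(m)
               if np.abs(R1[i, i]) <= rcond * max(svals.max(), 1.0)]
        raise ValueError(
            "constraints are rank deficient or inconsistent; offending rows: "
            + ", ".join(bad)
        )
    # particular solution in range(K^T), free part in the null space
    y1 = np.linalg.solve(R1.T, d)
    Q1, Q2 = Q[:, :m], Q[:, m:]
    du_part = Q1 @ y1
    if Q2.shape[1]:
        y2 = lstsq(A @ Q2, b - A @ du_part, cond=rcond, lapack_driver="gelsd")[0]
        du = du_part + Q2 @ y2
    else:
        du = du_part
    return scale * du


def selective_reduce(J: np.ndarray, residual: np.ndarray,
                     selection: Selection,
                     row_index: StackIndex, col_index: StackIndex,
                     weights: np.ndarray | None = None,
                     constraints: Sequence[ConstraintRow] = ()):
    """Drop columns of frozen potentials and rows of ignored targets.

    Returns ``(J_red, residual_red, weights_red, constraints_red,
    col_mask)``; scatter a reduced update back with ``du_full[col_mask] =
    du_red``.  The full Jacobian must be built first (HNC) — the
    reduction is purely an index operation.
    """
    row_mask = np.zeros(row_index.size, dtype=bool)
    for label in selection.target:
        row_mask[row_index.block(label)] = True
    col_mask = np.zeros(col_index.size, dtype=bool)
    for label in selection.update:
        col_mask[col_index.block(label)] = True
    J_red = J[np.ix_(row_mask, col_mask)]
    res_red = residual[row_mask]
    w_red = weights[row_mask] if weights is not None else None
    cons_red = [ConstraintRow(c.coeffs[col_mask], c.rhs, c.label)
                for c in constraints]
    return J_red, res_red, w_red, cons_red, col_mask


# ---------------------------------------------------------------------------
# thermodynamic properties


def _pair_prefactors(composition: Composition, label: InteractionLabel):
    rho_a = composition.density(label.a)
    rho_b = composition.density(label.b)
    delta = 1.0 if label.a == label.b else 0.0
    return rho_a, rho_b, delta


def virial_pressure(g: StackedField, u: StackedField, composition: Composition,
                    n_cut: int | None = None) -> float:
    """Virial pressure in bar.

    Ideal term ``sum_a rho_a kT`` plus the discrete pair-virial sum over
    half-shifted grid points,

        p = sum_a rho_a kT - (2 pi / 3) sum_{a<=b} (2 - d_ab)
            rho_a rho_b sum_i' r_i'^3 g(r_i') u'(r_i') dr,

    with midpoint RDF values by averaging and forces by the centred
    difference of the tabulated potential (zero beyond the cutoff).
    """
    grid: RadialGrid = g.grid
    nc = n_cut if n_cut is not None else grid.n_cut
    dr = grid.dr
    rmid = grid.midpoints[:nc]
    p = composition.total_density * composition.kT
    for label in g.labels:
        rho_a, rho_b, delta = _pair_prefactors(composition, label)
        gv = g[label].values
        uv = u[label].values.copy()
        uv[nc:] = 0.0
        gmid = 0.5 * (gv[:nc] + gv[1:nc + 1])
        force = (uv[1:nc + 1] - uv[:nc]) / dr  # du/dr at midpoints
        p -= (2.0 * np.pi / 3.0) * (2.0 - delta) * rho_a * rho_b * np.sum(
            rmid ** 3 * gmid * force) * dr
    return p * PRESSURE_TO_BAR


def kirkwood_buff(g: StackedField | Curve, n_res: int | None = None):
    """Kirkwood-Buff integral ``G = sum_i 4 pi r_i^2 (g_i - 1) dr`` in nm^3.

    Sums grid points ``i < n_res``.  Returns a float for a single curve
    and a dict over interactions for a stacked field.  Multiply by 1e3 to
    report in Angstrom^3.
    """
    if isinstance(g, Curve):
        grid = g.grid
        nr = n_res if n_res is not None else grid.n_res
        r = grid.r[:nr]
        return float(np.sum(4.0 * np.pi * r ** 2 * (g.values[:nr] - 1.0)) * grid.dr)
    return {label: kirkwood_buff(g[label], n_res) for label in g.labels}


def intermolecular_pe(g: StackedField, u: StackedField,
                      composition: Composition,
                      n_cut: int | None = None) -> float:
    """Intermolecular pair energy per bead, kJ/mol.

    ``PE/N = (1/N) sum_{a<=b} (2 - d_ab)/2 * (N_a N_b / V)
    sum_i 4 pi r_i^2 g_i u_i dr`` — intensive by construction.  Cohesive
    energy of the model, i.e. (minus) the vaporization enthalpy per bead
    up to ideal terms.  Valid for molecules without intramolecular pair
    potentials.
    """
    grid: RadialGrid = g.grid
    nc = n_cut if n_cut is not None else grid.n_cut
    N = sum(composition.counts.values())
    r = grid.r[:nc]
    total = 0.0
    for label in g.labels:
        na = composition.counts[label.a]
        nb = composition.counts[label.b]
        delta = 1.0 if label.a == label.b else 0.0
        gv = g[label].values[:nc]
        uv = u[label].values[:nc]
        total += ((2.0 - delta) / 2.0) * (na * nb / composition.volume) * np.sum(
            4.0 * np.pi * r ** 2 * gv * uv) * grid.dr
    return total / N


# ---------------------------------------------------------------------------
# constraint rows


def pressure_constraint(g_k: StackedField, u_k: StackedField,
                        composition: Composition, p_tgt: float,
                        index: StackIndex) -> ConstraintRow:
    """Row enforcing the virial pressure, ``d = p_k - p_tgt`` (bar).

    The pressure is linear in ``u`` at fixed ``g``, so the coefficients
    are exact; the RDF response ``dp/dg`` is neglected.
    """
    grid: RadialGrid = g_k.grid
    nc = index.n_bins + 1  # potential bins 1..n_bins, u[n_cut] pinned at 0
    dr = grid.dr
    rmid = grid.midpoints[:nc]
    coeffs = np.zeros(index.size)
    for I, label in enumerate(index.labels):
        rho_a, rho_b, delta = _pair_prefactors(composition, label)
        gv = g_k[label].values
        gmid = 0.5 * (gv[:nc] + gv[1:nc + 1])
        w = rmid ** 3 * gmid  # contribution weight of each midpoint force
        pref = (2.0 * np.pi / 3.0) * (2.0 - delta) * rho_a * rho_b
        # dp/du_j: u_j enters midpoints j-1 (as +u/dr) and j (as -u/dr)
        dpdu = np.empty(index.n_bins)
        for j in range(1, index.n_bins + 1):
            val = -w[j - 1]
            if j < nc:
                val += w[j]
            dpdu[j - 1] = pref * val
        # K = -dp/du so that K du = d drives p to target
        coeffs[I * index.n_bins:(I + 1) * index.n_bins] = -dpdu * PRESSURE_TO_BAR
    p_k = virial_pressure(g_k, u_k, composition, n_cut=nc)
    return ConstraintRow(coeffs, p_k - p_tgt, "pressure")


def kbi_constraint(g_k: StackedField, g_tgt: StackedField, J: np.ndarray,
                   row_index: StackIndex,
                   interactions: Sequence[InteractionLabel] | None = None,
                   n_res: int | None = None) -> list[ConstraintRow]:
    """Rows enforcing Kirkwood-Buff integrals through the RDF response.

    The KBI depends on ``g`` only, so the linearised constraint goes
    through the same Jacobian as the step: ``coeffs = -(dG/dg) J``
    restricted to the rows of the constrained interaction, with
    ``d = G_k - G_tgt`` (nm^3).  One row per interaction.
    """
    grid: RadialGrid = g_k.grid
    nr = n_res if n_res is not None else row_index.n_bins + 1
    labels = list(interactions) if interactions is not None else list(row_index.labels)
    rows = []
    for label in labels:
        if label not in row_index.labels:
            raise ValueError(f"interaction {label} not present in the system")
        dGdg = np.zeros(row_index.size)
        sl = row_index.block(label)
        r = grid.r[1:row_index.n_bins + 1]
        w = 4.0 * np.pi * r ** 2 * grid.dr
        w[r >= nr * grid.dr] = 0.0
        dGdg[sl] = w
        coeffs = -(dGdg @ J)
        G_k = kirkwood_buff(g_k[label], nr)
        G_tgt = kirkwood_buff(g_tgt[label], nr)
        rows.append(ConstraintRow(coeffs, G_k - G_tgt, f"kbi:{label}"))
    return rows


def pe_constraint(g_k: StackedField, u_k: StackedField,
                  composition: Composition, pe_tgt: float,
                  index: StackIndex) -> ConstraintRow:
    """Row enforcing the intermolecular potential energy per bead."""
    grid: RadialGrid = g_k.grid
    nc = index.n_bins + 1
    N = sum(composition.counts.values())
    coeffs = np.zeros(index.size)
    for I, label in enumerate(index.labels):
        na = composition.counts[label.a]
        nb = composition.counts[label.b]
        delta = 1.0 if label.a == label.b else 0.0
        r = grid.r[1:index.n_bins + 1]
        gv = g_k[label].values[1:index.n_bins + 1]
        dpe = ((2.0 - delta) / 2.0) * (na * nb / composition.volume) * (
            4.0 * np.pi * r ** 2 * gv * grid.dr) / N
        coeffs[I * index.n_bins:(I + 1) * index.n_bins] = -dpe
    pe_k = intermolecular_pe(g_k, u_k, composition, n_cut=nc)
    return ConstraintRow(coeffs, pe_k - pe_tgt, "pe")
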