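"""Symmetry-reduced RISM machinery.

The Ornstein-Zernike (OZ) equation defines the direct correlation function
``c`` implicitly; for molecules with bonded interaction sites it generalises
to the RISM equation, a per-wave-vector matrix identity over all sites,

    h' = w' c' w' + w' c' rho h',

where ``w'`` holds the intramolecular density functions (``sin(kb)/(kb)``
for a rigid site pair at distance ``b``) and ``rho`` the per-site number
densities.  When a molecule contains ``n_a`` indistinguishable sites of
type ``a``, a block-orthogonal similarity transformation (first column of
each block ``n_a**-1/2``) collapses the site matrices to bead-*type*
matrices.  Because trajectory analysis produces site-averaged functions
``h`` rather than site-resolved ``h'``, the explicit transformation is
never needed; the reduced matrices follow from simple multiplicity
factors:

    H_ab = sqrt(n_a n_b) h_ab,     C_ab = sqrt(n_a n_b) c_ab,
    W_ab = (n_a n_b)**-1/2 * sum over site pairs of w'_ss',

with the per-site density ``rho_a = N_a / (n_a V)`` (the molecule number
density).  The reduced RISM equation then reads ``H = W C W + W C rho H``
with ``n_t x n_t`` matrices, and solving it for ``C`` gives

    C = W^-1 H (W + rho H)^-1.

Differentiating that map and vectorising (``vec(U V W) = (W^T (x) U)
vec(V)``) yields the per-k derivative ``dC/dH`` needed by the
hypernetted-chain (HNC) Newton schemes; conjugating with the radial
Fourier matrix turns it into the real-space operator ``dc/dh``.

The HNC closure ``g = exp(-u/kT + h - c)`` inverts to the potential guess

    u = kT * (h - c - ln g).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grids import (
    Curve,
    InteractionLabel,
    KGrid,
    RadialGrid,
    StackedField,
    Composition,
    fourier_matrix,
    interaction_labels,
    inverse_fourier_matrix,
    radial_ft,
    radial_ift,
)

__all__ = [
    "MoleculeGraph",
    "IntraMolecularMatrix",
    "ReducedCorrelations",
    "DcDhOperator",
    "build_omega",
    "reduce_correlations",
    "restore_correlations",
    "direct_correlation",
    "solve_rism_h",
    "hnc_guess",
    "cut_and_shift",
    "dcdh_k",
    "dcdh_real",
]


class SingularRismError(np.linalg.LinAlgError):
    """A RISM matrix was singular at some wave vector."""

    def __init__(self, k: float, what: str):
        super().__init__(f"{what} is singular at k = {k:.6g} nm^-1")
        self.k = k


def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with the analytic limit 1 at x = 0."""
    return np.sinc(x / np.pi)


@dataclass
class MoleculeGraph:
    """One molecular species: sites, types and intramolecular distances.

    ``sites`` is the ordered list of bead-type labels, one per site.
    ``distances`` maps site-index pairs to either a fixed distance in nm
    (rigid molecule) or a normalised distance-distribution
    :class:`~cginvert.grids.Curve`.  Every distinct site pair must be
    specified unless the molecule has a single site.
    """

    sites: Sequence[str]
    distances: Mapping[tuple[int, int], float | Curve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        dist = {}
        for (i, j), spec in dict(self.distances).items():
            if i == j:
                raise ValueError("a site has no distance to itself")
            dist[(min(i, j), max(i, j))] = spec
        self.distances = dist
        n = len(self.sites)
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) not in dist:
                    raise ValueError(
                        f"missing intramolecular distance for site pair ({i}, {j})"
                    )

    @property
    def types(self) -> list[str]:
        return sorted(set(self.sites))

    @property
    def multiplicities(self) -> dict[str, int]:
        """Number of indistinguishable sites per bead type, n_alpha."""
        out: dict[str, int] = {}
        for s in self.sites:
            out[s] = out.get(s, 0) + 1
        return out

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def omega_pair(self, i: int, j: int, k: np.ndarray) -> np.ndarray:
        """Intramolecular density function of one site pair on a k grid."""
        if i == j:
            return np.ones_like(k)
        spec = self.distances[(min(i, j), max(i, j))]
        if isinstance(spec, Curve):
            grid = spec.grid
            if not isinstance(grid, RadialGrid):
                raise ValueError("distance distributions live on a radial grid")
            b = grid.r
            w = spec.values * grid.dr
            return np.array([np.sum(w * _sinc(kk * b)) for kk in k])
        return _sinc(k * float(spec))


def single_bead(type_name: str) -> MoleculeGraph:
    return MoleculeGraph(sites=[type_name])


@dataclass
class IntraMolecularMatrix:
    """Symmetry-reduced intramolecular matrix W(k), one n_t x n_t block per k."""

    kgrid: KGrid
    types: list[str]
    multiplicities: dict[str, int]
    values: np.ndarray  # shape (n_k, n_t, n_t)

    @property
    def n_types(self) -> int:
        return len(self.types)

    def site_density(self, composition: Composition) -> np.ndarray:
        """Diagonal per-site densities rho_a = N_a / (n_a V), in type order."""
        return np.array(
            [composition.counts[t] / (self.multiplicities[t] * composition.volume)
             for t in self.types]
        )


def build_omega(molecules: MoleculeGraph | Sequence[MoleculeGraph],
                kgrid: KGrid) -> IntraMolecularMatrix:
    """Assemble the reduced intramolecular matrix for one or more species.

    Species share no bead types; their blocks are decoupled (sites on
    different molecules have no intramolecular correlation).
    """
    if isinstance(molecules, MoleculeGraph):
        molecules = [molecules]
    types: list[str] = []
    mult: dict[str, int] = {}
    owner: dict[str, MoleculeGraph] = {}
    for mol in molecules:
        for t, n in mol.multiplicities.items():
            if t in mult:
                raise ValueError(f"bead type {t!r} appears in two species")
            mult[t] = n
            owner[t] = mol
    types = sorted(mult)
    k = kgrid.k
    nt = len(types)
    vals = np.zeros((kgrid.n_points, nt, nt))
    for ia, a in enumerate(types):
        for ib, b in enumerate(types[ia:], start=ia):
            if owner[a] is not owner[b]:
                continue
            mol = owner[a]
            acc = np.zeros_like(k)
            for si, st in enumerate(mol.sites):
                if st != a:
                    continue
                for sj, st2 in enumerate(mol.sites):
                    if st2 != b:
                        continue
                    acc += mol.omega_pair(si, sj, k)
            acc /= np.sqrt(mult[a] * mult[b])
            vals[:, ia, ib] = acc
            vals[:, ib, ia] = acc
    return IntraMolecularMatrix(kgrid, types, mult, vals)


@dataclass
class ReducedCorrelations:
    """Symmetry-reduced total-correlation matrices H(k) (and optionally C)."""

    kgrid: KGrid
    types: list[str]
    multiplicities: dict[str, int]
    H: np.ndarray  # (n_k, n_t, n_t)

    @property
    def labels(self) -> list[InteractionLabel]:
        return interaction_labels(self.types)


def _mult_factor(mult: dict[str, int], label: InteractionLabel) -> float:
    return float(np.sqrt(mult[label.a] * mult[label.b]))


def reduce_correlations(h: StackedField, omega: IntraMolecularMatrix,
                        composition: Composition | None = None) -> ReducedCorrelations:
    """Fourier-transform site-averaged h and apply the multiplicity factors."""
    types = omega.types
    if sorted({t for l in h.labels for t in (l.a, l.b)}) != types:
        raise ValueError("bead types of h do not match the molecule spec")
    kg = h.grid.k_grid()
    nt = len(types)
    H = np.zeros((kg.n_points, nt, nt))
    index = {t: i for i, t in enumerate(types)}
    for label in h.labels:
        hk = radial_ft(h[label]).values
        val = _mult_factor(omega.multiplicities, label) * hk
        ia, ib = index[label.a], index[label.b]
        H[:, ia, ib] = val
        H[:, ib, ia] = val
    return ReducedCorrelations(kg, types, dict(omega.multiplicities), H)


def restore_correlations(reduced: np.ndarray, omega: IntraMolecularMatrix,
                         grid: RadialGrid, kind: str = "correlation") -> StackedField:
    """Invert the reduction: reduced k-space matrices -> site-averaged curves."""
    labels = interaction_labels(omega.types)
    index = {t: i for i, t in enumerate(omega.types)}
    curves = []
    kg = grid.k_grid()
    for label in labels:
        ia, ib = index[label.a], index[label.b]
        sym = 0.5 * (reduced[:, ia, ib] + reduced[:, ib, ia])
        xk = sym / _mult_factor(omega.multiplicities, label)
        curves.append(radial_ift(Curve(kg, xk, kind), grid))
    return StackedField(labels, curves)


def _solve_stack(A: np.ndarray, B: np.ndarray, k: np.ndarray,
                 what: str) -> np.ndarray:
    """Per-k solve of ``A X = B``, continuing the k = 0 slice (see
    :func:`_invert_stack`)."""
    out = np.empty_like(B)
    try:
        out[1:] = np.linalg.solve(A[1:], B[1:])
    except np.linalg.LinAlgError:
        for j in range(1, A.shape[0]):  # pragma: no cover - diagnostic
            if abs(np.linalg.det(A[j])) < 1e-300:
                raise SingularRismError(k[j], what) from None
        raise
    out[0] = out[1]
    return out


def _invert_stack(mats: np.ndarray, k: np.ndarray, what: str) -> np.ndarray:
    """Per-k inverses, skipping k = 0.

    The intramolecular matrix of a rigid molecule is rank-deficient at
    zero wave vector (every sin(kb)/(kb) tends to 1), so the k = 0 slice
    is continued from the first interior wave vector.  Only the r = 0
    grid bin — which carries no weight in the radial transforms — is
    affected.
    """
    out = np.empty_like(mats)
    try:
        out[1:] = np.linalg.inv(mats[1:])
    except np.linalg.LinAlgError:
        for j in range(1, mats.shape[0]):  # pragma: no cover - diagnostic
            if abs(np.linalg.det(mats[j])) < 1e-300:
                raise SingularRismError(k[j], what) from None
        raise
    out[0] = out[1]
    return out


def direct_correlation(h: StackedField | ReducedCorrelations,
                       omega: IntraMolecularMatrix,
                       composition: Composition,
                       grid: RadialGrid | None = None) -> StackedField:
    """Direct correlation function from the total correlation function.

    Solves the reduced RISM equation for ``C = W^-1 H (W + rho H)^-1`` at
    every wave vector, undoes the reduction and transforms back to real
    space.
    """
    if isinstance(h, StackedField):
        if grid is None:
            grid = h.grid
        H = reduce_correlations(h, omega, composition)
    else:
        H = h
        if grid is None:
            raise ValueError("grid required when starting from reduced matrices")
    rho = omega.site_density(composition)
    k = H.kgrid.k
    # Z = W + rho*H with the diagonal density acting from the left
    Z = omega.values + rho[None, :, None] * H.H
    # C = W^-1 H Z^-1 via two linear solves (better conditioned than
    # explicit inverses near the almost-singular small-k matrices)
    X = _solve_stack(omega.values, H.H, k, "the intramolecular matrix")
    C = np.transpose(
        _solve_stack(np.transpose(Z, (0, 2, 1)), np.transpose(X, (0, 2, 1)),
                     k, "W + rho*H"),
        (0, 2, 1),
    )
    C = 0.5 * (C + np.transpose(C, (0, 2, 1)))
    return restore_correlations(C, omega, grid)


def solve_rism_h(C: np.ndarray, omega: IntraMolecularMatrix,
                 composition: Composition) -> np.ndarray:
    """Forward RISM: reduced H(k) from reduced C(k).

    Inverts ``H = W C W + W C rho H`` to ``H = (I - W C rho)^-1 W C W``.
    """
    rho = omega.site_density(composition)
    W = omega.values
    WC = W @ C
    nt = W.shape[-1]
    eye = np.eye(nt)[None, :, :]
    A = eye - WC * rho[None, None, :]
    H = _invert_stack(A, omega.kgrid.k, "I - W*C*rho") @ (WC @ W)
    return 0.5 * (H + np.transpose(H, (0, 2, 1)))


def cut_and_shift(u: StackedField, n_cut: int) -> StackedField:
    """Cut a stacked potential at the cutoff and shift it to zero beyond."""
    def _cs(v: np.ndarray) -> np.ndarray:
        out = v - v[n_cut]
        out[n_cut:] = 0.0
        return out
    return u.map(_cs, kind="potential")


def hnc_guess(g: StackedField, c: StackedField, kT: float,
              n_cut: int | None = None) -> StackedField:
    """Potential from the HNC closure, ``u = kT (h - c - ln g)``.

    The RDFs must be strictly positive on the evaluated range (run the
    onset extrapolation first); ``u_ab`` and ``u_ba`` coincide in the
    site-averaged representation, so the symmetrisation is implicit.  The
    result is cut at ``n_cut`` grid points and shifted to zero beyond.
    """
    curves = []
    for label in g.labels:
        gv = g[label].values
        cv = c[label].values
        lo = n_cut if n_cut is not None else len(gv)
        if np.any(gv[1:lo] <= 0):
            raise ValueError(
                f"g({label}) vanishes inside the evaluation range; "
                "extrapolate the RDF onset first"
            )
        with np.errstate(divide="ignore"):
            u = kT * ((gv - 1.0) - cv - np.log(np.where(gv > 0, gv, 1e-300)))
        curves.append(Curve(g[label].grid, u, "potential"))
    stacked = StackedField(list(g.labels), curves)
    if n_cut is not None:
        stacked = cut_and_shift(stacked, n_cut)
    return stacked


@dataclass
class DcDhOperator:
    """Per-wave-vector derivative of c with respect to h.

    ``values[j, I, J]`` is the scalar ``dc_I(k_j)/dh_J(k_j)`` for the
    unordered interactions ``I`` and ``J`` (the ab/ba duplicates are
    already merged: rows averaged, columns summed).
    """

    grid: RadialGrid
    labels: list[InteractionLabel]
    values: np.ndarray  # (n_k, n_i, n_i)


def dcdh_k(h: StackedField | ReducedCorrelations, omega: IntraMolecularMatrix,
           composition: Composition, grid: RadialGrid | None = None) -> DcDhOperator:
    """Per-k linear map dC/dH, merged to unordered interactions.

    From ``C = W^-1 H Z^-1`` with ``Z = W + rho H``, a first-order
    perturbation gives ``dC = U dH Z^-1`` with
    ``U = W^-1 (I - H Z^-1 rho)``, i.e. the ordered element
    ``dC_ab/dH_ge = U_ag (Z^-1)_eb``.  Multiplicity factors convert the
    reduced derivative to the site-averaged one; rows (ab)/(ba) are
    averaged and columns (ge)/(eg) summed.
    """
    if isinstance(h, StackedField):
        if grid is None:
            grid = h.grid
        H = reduce_correlations(h, omega, composition)
    else:
        H = h
        if grid is None:
            raise ValueError("grid required when starting from reduced matrices")
    rho = omega.site_density(composition)
    k = H.kgrid.k
    Z = omega.values + rho[None, :, None] * H.H
    Zinv = _invert_stack(Z, k, "W + rho*H")
    Winv = _invert_stack(omega.values, k, "the intramolecular matrix")
    # U = W^-1 (I - H Z^-1 rho); rho acts as a diagonal matrix from the right
    HZr = (H.H @ Zinv) * rho[None, None, :]
    nt = len(omega.types)
    U = Winv @ (np.eye(nt)[None, :, :] - HZr)
    labels = interaction_labels(omega.types)
    index = {t: i for i, t in enumerate(omega.types)}
    n_i = len(labels)
    D = np.zeros((H.kgrid.n_points, n_i, n_i))
    mult = omega.multiplicities

    def ordered(a, b, gam, eps):
        return U[:, a, gam] * Zinv[:, eps, b]

    for I, li in enumerate(labels):
        a, b = index[li.a], index[li.b]
        for J, lj in enumerate(labels):
            gam, eps = index[lj.a], index[lj.b]
            f = np.sqrt(mult[lj.a] * mult[lj.b]) / np.sqrt(mult[li.a] * mult[li.b])
            val = 0.5 * (ordered(a, b, gam, eps) + ordered(b, a, gam, eps))
            if gam != eps:
                val += 0.5 * (ordered(a, b, eps, gam) + ordered(b, a, eps, gam))
            D[:, I, J] = f * val
    return DcDhOperator(grid, labels, D)


def dcdh_real(op: DcDhOperator, n_bins: int | None = None) -> np.ndarray:
    """Real-space derivative matrix by conjugation with the Fourier matrix.

    Returns the dense block matrix over (interaction, interior grid point)
    with blocks ``F^-1 diag(dc/dh(k)) F``; if ``n_bins`` is given, rows
    and columns are truncated to the first ``n_bins`` interior points.
    When the operator is precomputed from target data, curves of (at
    least) double the working length should be used to avoid truncation
    artifacts.
    """
    grid = op.grid
    m_full = grid.n_points - 1
    m = n_bins if n_bins is not None else m_full
    if m > m_full:
        raise ValueError("n_bins exceeds the operator's grid")
    F = fourier_matrix(grid)
    Finv = inverse_fourier_matrix(grid)
    n_i = len(op.labels)
    out = np.empty((n_i * m, n_i * m))
    for I in range(n_i):
        for J in range(n_i):
            d = op.values[1:, I, J]
            block = (Finv * d[None, :]) @ F
            out[I * m:(I + 1) * m, J * m:(J + 1) * m] = block[:m, :m]
    return out
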