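"""Self-consistent RISM + HNC structure solver and synthetic-data factory.

This module stands in for molecular dynamics as the forward model of the
inverse problem: given pair potentials it produces RDFs by iterating the
reduced RISM equation (for ``h`` given ``c``) against the HNC closure
``g = exp(-u/kT + h - c)`` with Picard mixing, to a deterministic fixed
point.  It also generates the synthetic noise and particle-count
ensembles the estimator tests need:

* finite-sampling RDF noise with per-bin standard deviation
  ``sqrt(g / (4 pi r^2 dr rho N n_frames))`` — the Poisson-counting
  scaling of a histogram estimator, reproducible by seed;
* multivariate-normal pair-count vectors with prescribed moments for the
  inverse-Monte-Carlo covariance estimator.

The toy systems bundle a single-bead Lennard-Jones fluid, the
neon-argon 1:1 mixture (sigma_Ne = 0.278 nm, eps_Ne = 0.28869 kJ/mol,
sigma_Ar = 0.3401 nm, eps_Ar = 0.978628 kJ/mol, T = 100 K) and a rigid
symmetric A-B-A trimer fluid exercising the symmetry-reduced RISM path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Composition, Curve, RadialGrid, StackedField, interaction_labels
from .rism import (
    IntraMolecularMatrix,
    MoleculeGraph,
    build_omega,
    reduce_correlations,
    restore_correlations,
    solve_rism_h,
)

__all__ = [
    "SolverSettings",
    "ConvergenceError",
    "solve_structure",
    "SurrogateForward",
    "lj_table",
    "add_sampling_noise",
    "sample_imc_ensemble",
    "ToySystem",
    "toy_systems",
]


class ConvergenceError(RuntimeError):
    """Picard iteration failed; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class SolverSettings:
    """Picard settings for the structure solver."""

    mixing: float = 0.2
    tolerance: float = 1e-10
    max_iterations: int = 50000
    #: bail out early once the residual exceeds this bound (a diverging
    #: Picard iteration never recovers; failing fast keeps damped-update
    #: drivers responsive)
    divergence_bound: float = 1e7

    def __post_init__(self) -> None:
        if not 0 < self.mixing <= 1:
            raise ValueError("mixing factor must be in (0, 1]")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")


def solve_structure(u: StackedField, composition: Composition,
                    omega: IntraMolecularMatrix,
                    settings: SolverSettings | None = None,
                    return_c: bool = False,
                    c_start: StackedField | None = None):
    """Fixed point of RISM (h from c) alternated with the HNC closure.

    Deterministic given its inputs; converges on ``max |g_new - g| <
    tolerance``.  Returns the RDF stack (and optionally the direct
    correlation functions at the fixed point).

    ``c_start`` warm-starts the iteration from a previous solution's
    direct correlation functions; without it the Mayer function
    ``exp(-u/kT) - 1`` is used.  Warm starting keeps the solved branch
    continuous along a sequence of nearby potentials, the way a
    molecular-dynamics forward model tracks its state.
    """
    if settings is None:
        settings = SolverSettings()
    grid: RadialGrid = u.grid
    beta = composition.beta
    labels = list(u.labels)
    bu = {label: beta * u[label].values for label in labels}
    boltz = {label: np.exp(np.minimum(-bu[label], 60.0)) for label in labels}
    if c_start is not None:
        c = {label: c_start[label].values.copy() for label in labels}
    else:
        # low-density start: c = e^{-beta u} - 1 (Mayer function)
        c = {label: boltz[label] - 1.0 for label in labels}
    g_old = {label: boltz[label].copy() for label in labels}
    history: list[float] = []
    for iteration in range(settings.max_iterations):
        c_stack = StackedField(
            labels, [Curve(grid, c[l], "correlation") for l in labels]
        )
        C = reduce_correlations(c_stack, omega, composition).H
        H = solve_rism_h(C, omega, composition)
        h_stack = restore_correlations(H, omega, grid)
        resid = 0.0
        for label in labels:
            gamma = h_stack[label].values - c[label]
            # exponent clipped only against transient overflow during mixing
            g_new = np.exp(np.minimum(gamma - bu[label], 60.0))
            c_new = g_new - 1.0 - gamma
            resid = max(resid, float(np.max(np.abs(g_new - g_old[label]))))
            c[label] = c[label] + settings.mixing * (c_new - c[label])
            g_old[label] = g_new
        history.append(resid)
        if resid < settings.tolerance:
            break
        if not np.isfinite(resid) or resid > settings.divergence_bound:
            raise ConvergenceError(
                f"structure solver diverged (residual {resid:.3g} after "
                f"{iteration + 1} iterations)", history,
            )
    else:
        raise ConvergenceError(
            f"structure solver did not reach {settings.tolerance:g} in "
            f"{settings.max_iterations} iterations (last residual "
            f"{history[-1]:.3g})", history,
        )
    g = StackedField(labels, [Curve(grid, np.clip(g_old[l], 0.0, None), "rdf")
                              for l in labels])
    g.residual_history = history  # type: ignore[attr-defined]
    if return_c:
        c_stack = StackedField(
            labels, [Curve(grid, c[l], "correlation") for l in labels]
        )
        return g, c_stack
    return g


def lj_table(sigma: float, epsilon: float, grid: RadialGrid,
             r_cut: float | None = None, shifted: bool = False,
             u_max: float = 1e6) -> Curve:
    """Lennard-Jones table ``4 eps [(sigma/r)^12 - (sigma/r)^6]``.

    Values are capped at ``u_max`` near ``r = 0``; with ``shifted=True``
    the potential is raised to be exactly zero at ``r_cut`` and beyond.
    """
    r = grid.r
    with np.errstate(divide="ignore", over="ignore"):
        sr6 = (sigma / np.where(r > 0, r, np.nan)) ** 6
        u = 4.0 * epsilon * (sr6 ** 2 - sr6)
    u[0] = u_max
    u = np.minimum(np.nan_to_num(u, nan=u_max, posinf=u_max), u_max)
    if shifted:
        if r_cut is None:
            r_cut = grid.r_cut
        n_cut = int(round(r_cut / grid.dr))
        sr6c = (sigma / r_cut) ** 6
        u_cut = 4.0 * epsilon * (sr6c ** 2 - sr6c)
        u = u - u_cut
        u[n_cut:] = 0.0
        u = np.minimum(u, u_max)
    return Curve(grid, u, "potential")


def add_sampling_noise(g: Curve, composition: Composition, n_frames: int,
                       seed: int) -> Curve:
    """Multiplicative finite-sampling noise on an RDF, reproducible by seed.

    Per-bin standard deviation ``sqrt(g / (4 pi r^2 dr rho N n_frames))``
    — the relative noise grows where the shell volume or the RDF itself
    is small, and decays as the inverse square root of the frame count.
    Negative results are clipped to zero.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    grid: RadialGrid = g.grid
    rng = np.random.default_rng(seed)
    r = grid.r
    sigma = np.zeros(grid.n_points)
    shell = 4.0 * np.pi * r[1:] ** 2 * grid.dr
    norm = composition.total_density * sum(composition.counts.values()) * n_frames
    sigma[1:] = np.sqrt(g.values[1:] / (shell * norm))
    noisy = g.values + sigma * rng.standard_normal(grid.n_points)
    return Curve(grid, np.clip(noisy, 0.0, None), "rdf")


def sample_imc_ensemble(mean: np.ndarray, covariance: np.ndarray,
                        n_frames: int, seed: int) -> np.ndarray:
    """Draw pair-count vectors from a multivariate normal, seeded."""
    mean = np.asarray(mean, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(mean, covariance, size=n_frames,
                                   method="svd")


class SurrogateForward:
    """Forward-model adapter for the iteration driver.

    Wraps :func:`solve_structure` with warm starting (each call starts
    the Picard iteration from the previous direct correlation functions,
    the way an MD forward model carries its configuration between
    iterations), optional finite-sampling noise, and synthetic
    pair-count statistics for the inverse-Monte-Carlo methods.
    """

    def __init__(self, composition: Composition, omega: IntraMolecularMatrix,
                 settings: SolverSettings | None = None,
                 noise_frames: int | None = None, seed: int = 0,
                 u_target: StackedField | None = None):
        self.composition = composition
        self.omega = omega
        self.settings = settings or SolverSettings()
        self.noise_frames = noise_frames
        self.seed = seed
        self.u_target = u_target
        self._c_cache: StackedField | None = None
        self._calls = 0

    def __call__(self, u: StackedField) -> StackedField:
        g, c = solve_structure(u, self.composition, self.omega, self.settings,
                               return_c=True, c_start=self._c_cache)
        self._c_cache = c
        self._calls += 1
        if self.noise_frames:
            curves = [
                add_sampling_noise(g[l], self.composition, self.noise_frames,
                                   seed=self.seed + 7919 * self._calls + i)
                for i, l in enumerate(g.labels)
            ]
            g = StackedField(list(g.labels), curves)
        return g

    def imc_statistics(self, u: StackedField | None, n_frames: int,
                       seed: int):
        """Synthetic pair-count statistics consistent with the solver.

        The exact RDF response matrix of the surrogate (via the HNC
        closure derivative) fixes the count covariance up to
        symmetrisation; finite ensembles of multivariate-normal count
        vectors then reproduce the sampling noise of a real IMC
        estimate.  ``u = None`` evaluates at the reference (target)
        potential, the t-IMC shortcut.
        """
        from .jacobians import (StackIndex, jacobian_hnc,
                                pair_count_factors)
        from .rism import dcdh_k, dcdh_real
        if u is None:
            if self.u_target is None:
                raise ValueError("no reference potential available for "
                                 "target-ensemble statistics")
            u = self.u_target
        g = solve_structure(u, self.composition, self.omega, self.settings,
                            c_start=self._c_cache)
        grid = u.grid
        m = grid.n_res - 1
        idx = StackIndex(tuple(u.labels), m)
        h = g.map(lambda v: v - 1.0, kind="correlation")
        D = dcdh_real(dcdh_k(h, self.omega, self.composition), n_bins=m)
        kT = self.composition.kT
        # floor the core so the closure diagonal stays finite; the count
        # covariance there is negligible anyway (counts are ~ zero)
        g_floor = g.map(lambda v: np.maximum(v, 1e-12), kind="rdf")
        Jinv = jacobian_hnc(g_floor, g_floor, D, kT, idx)
        J = np.linalg.inv(Jinv)
        fac = pair_count_factors(self.composition, grid, idx)
        from .jacobians import flatten_bins
        mean_S = fac * flatten_bins(g, idx)
        cov = -kT * fac[:, None] * J
        cov = 0.5 * (cov + cov.T)
        w, V = np.linalg.eigh(cov)
        cov = (V * np.clip(w, 0.0, None)) @ V.T
        # accumulate moments chunk-wise so large ensembles never
        # materialize in memory
        dim = mean_S.size
        mean_acc = np.zeros(dim)
        second_acc = np.zeros((dim, dim))
        chunk = 20000
        done = 0
        part = 0
        while done < n_frames:
            take = min(chunk, n_frames - done)
            s = sample_imc_ensemble(mean_S, cov, take, seed + 131 * part)
            mean_acc += s.sum(axis=0)
            second_acc += s.T @ s
            done += take
            part += 1
        mean_acc /= n_frames
        second_acc /= n_frames
        from .jacobians import ImcStats
        return ImcStats(idx, mean_acc, 0.5 * (second_acc + second_acc.T),
                        n_frames)


# ---------------------------------------------------------------------------
# toy systems


@dataclass
class ToySystem:
    """A named desk-scale system: molecules, state point, grid, potentials."""

    name: str
    molecules: list[MoleculeGraph]
    composition: Composition
    grid: RadialGrid
    u_true: StackedField
    omega: IntraMolecularMatrix = field(init=False)

    def __post_init__(self) -> None:
        self.omega = build_omega(self.molecules, self.grid.k_grid())

    def solve(self, u: StackedField | None = None,
              settings: SolverSettings | None = None, **kw):
        return solve_structure(u if u is not None else self.u_true,
                               self.composition, self.omega, settings, **kw)

    def forward(self, settings: SolverSettings | None = None,
                **kw) -> "SurrogateForward":
        """Driver-ready forward model for this system."""
        return SurrogateForward(self.composition, self.omega,
                                settings or SolverSettings(max_iterations=30000),
                                u_target=self.u_true, **kw)


NE_SIGMA, NE_EPS = 0.278, 0.28869      # nm, kJ/mol
AR_SIGMA, AR_EPS = 0.3401, 0.978628


def toy_systems() -> dict[str, ToySystem]:
    """The bundled desk-scale fixtures."""
    systems: dict[str, ToySystem] = {}

    # (a) single-bead Lennard-Jones fluid
    grid_a = RadialGrid.from_lengths(dr=0.004, r_max=2.048, r_cut=1.0)
    comp_a = Composition(counts={"A": 2250}, volume=125.0, temperature=100.0)
    u_a = StackedField(
        interaction_labels(["A"]),
        [lj_table(AR_SIGMA, AR_EPS, grid_a, r_cut=1.0, shifted=True)],
    )
    systems["lj_fluid"] = ToySystem(
        "lj_fluid", [MoleculeGraph(sites=["A"])], comp_a, grid_a, u_a
    )

    # (b) neon-argon 1:1 mixture on its 0.002 nm production grid.  The
    # state point sits on the dilute branch: at 100 K this mixture is
    # close to its plait point over a wide range of intermediate
    # densities, where the homogeneous integral equations lose their
    # solution for off-optimal potentials; the dilute branch keeps the
    # full inverse problem well posed end to end.
    grid_b = RadialGrid.from_lengths(dr=0.002, r_max=2.4, r_cut=0.9)
    comp_b = Composition(counts={"Ar": 250, "Ne": 250}, volume=250.0,
                         temperature=100.0)
    labels_b = interaction_labels(["Ne", "Ar"])
    params = {
        ("Ar", "Ar"): (AR_SIGMA, AR_EPS),
        ("Ne", "Ne"): (NE_SIGMA, NE_EPS),
        # geometric combination for the cross interaction
        ("Ar", "Ne"): (np.sqrt(AR_SIGMA * NE_SIGMA), np.sqrt(AR_EPS * NE_EPS)),
    }
    curves_b = [
        lj_table(*params[(l.a, l.b)], grid_b, r_cut=grid_b.r_cut, shifted=True)
        for l in labels_b
    ]
    systems["ne_ar"] = ToySystem(
        "ne_ar",
        [MoleculeGraph(sites=["Ne"]), MoleculeGraph(sites=["Ar"])],
        comp_b, grid_b, StackedField(labels_b, curves_b),
    )

    # (c) rigid symmetric A-B-A trimer (hexane-like three-bead molecule)
    grid_c = RadialGrid.from_lengths(dr=0.005, r_max=2.56, r_cut=1.2)
    comp_c = Composition(counts={"A": 1000, "B": 500}, volume=160.0,
                         temperature=300.0)
    bond = 0.25
    trimer = MoleculeGraph(
        sites=["A", "B", "A"],
        distances={(0, 1): bond, (1, 2): bond, (0, 2): 2.0 * bond},
    )
    labels_c = interaction_labels(["A", "B"])
    lj_c = {
        ("A", "A"): (0.40, 0.6),
        ("A", "B"): (0.38, 0.5),
        ("B", "B"): (0.36, 0.45),
    }
    curves_c = [
        lj_table(*lj_c[(l.a, l.b)], grid_c, r_cut=grid_c.r_cut, shifted=True)
        for l in labels_c
    ]
    systems["trimer"] = ToySystem(
        "trimer", [trimer], comp_c, grid_c, StackedField(labels_c, curves_c)
    )
    return systems
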