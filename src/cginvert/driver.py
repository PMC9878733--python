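"""The coarse-graining iteration loop and its method registry.

A *method name* is a base update scheme with optional prefixes::

    [p-][PE-][KBI-][t-]{IBI | HNCN | HNCGN | IMC | IMCGN}

* ``IBI``    — iterative Boltzmann inversion, diagonal logarithmic update.
* ``HNCN``   — Newton with the hypernetted-chain Jacobian inverse.
* ``HNCGN``  — weighted (optionally constrained) Gauss-Newton with the
  HNC Jacobian.
* ``IMC``    — Newton with the Jacobian sampled from particle-count
  cross-correlations; ``IMCGN`` the Gauss-Newton variant.
* ``t-``     — the closure derivative (HNC) or count statistics (IMC)
  are computed once at the target and reused every iteration.
* ``p-``, ``PE-``, ``KBI-`` — constrain the virial pressure, the
  intermolecular potential energy per bead, or the Kirkwood-Buff
  integrals of all nonbonded interactions in every update.

One iteration (the flow of the method): evaluate the forward model,
extrapolate the RDF onsets, build (or reuse) the Jacobian, assemble the
constraint rows, solve the update, scale, apply, shift the potential to
zero at the cutoff, and log the metrics.  When bonded terms are present
the loop alternates: even iterations update the nonbonded potentials,
odd iterations apply distribution-IBI to the bonded ones (simultaneous
updates of both are oscillation-prone and only available explicitly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np

from .grids import (
    Composition,
    Curve,
    InteractionLabel,
    RadialGrid,
    StackedField,
)
from .jacobians import (
    ImcStats,
    OnsetPolicy,
    StackIndex,
    flatten_bins,
    ibi_update,
    improve_imc,
    jacobian_hnc,
    jacobian_imc,
    unflatten_bins,
)
from .prep import OnsetFitWindow, chi_g, extrapolate_all
from .rism import (
    IntraMolecularMatrix,
    cut_and_shift,
    dcdh_k,
    dcdh_real,
    direct_correlation,
    hnc_guess,
)
from .updates import (
    ConstraintRow,
    Selection,
    ThermoTargets,
    default_weights,
    gauss_newton_step,
    intermolecular_pe,
    kbi_constraint,
    kirkwood_buff,
    newton_step,
    pe_constraint,
    pressure_constraint,
    selective_reduce,
    virial_pressure,
)

__all__ = [
    "RunConfig",
    "IterationState",
    "DivergenceError",
    "parse_method",
    "initial_guess",
    "run_iteration",
    "run_loop",
]

BASE_METHODS = ("IBI", "HNCN", "HNCGN", "IMC", "IMCGN")
PREFIXES = ("p", "PE", "KBI", "t")


class DivergenceError(RuntimeError):
    """The RDF mismatch grew for several consecutive iterations."""


@dataclass(frozen=True)
class MethodSpec:
    base: str
    one_time: bool = False          # t- variant
    constrain_pressure: bool = False
    constrain_pe: bool = False
    constrain_kbi: bool = False

    @property
    def is_gauss_newton(self) -> bool:
        return self.base in ("HNCGN", "IMCGN")

    @property
    def uses_hnc(self) -> bool:
        return self.base in ("HNCN", "HNCGN")

    @property
    def uses_imc(self) -> bool:
        return self.base in ("IMC", "IMCGN")

    @property
    def constrained(self) -> bool:
        return self.constrain_pressure or self.constrain_pe or self.constrain_kbi


def parse_method(name: str) -> MethodSpec:
    """Parse a method name like ``KBI-p-t-HNCGN`` into its components."""
    tokens = name.split("-")
    base = tokens[-1].upper()
    if base not in BASE_METHODS:
        raise ValueError(f"unknown base method {tokens[-1]!r}; "
                         f"choose from {BASE_METHODS}")
    spec = MethodSpec(base=base)
    for tok in tokens[:-1]:
        if tok == "t":
            spec = replace(spec, one_time=True)
        elif tok == "p":
            spec = replace(spec, constrain_pressure=True)
        elif tok.upper() == "PE":
            spec = replace(spec, constrain_pe=True)
        elif tok.upper() == "KBI":
            spec = replace(spec, constrain_kbi=True)
        else:
            raise ValueError(f"unknown method prefix {tok!r} in {name!r}")
    if spec.constrained and not spec.is_gauss_newton:
        raise ValueError("thermodynamic constraints require a Gauss-Newton "
                         "method (HNCGN or IMCGN)")
    return spec


@dataclass
class RunConfig:
    """Everything one iteration run needs besides the forward model."""

    method: str = "HNCN"
    max_iterations: int = 10
    initial_guess: str = "hnc"              # pmf | hnc | avg
    onset_lower: float = 0.001
    onset_upper: float = 0.1
    imc_t1: float = 0.001
    imc_t2: float = 0.1
    weighting: str = "default"              # default | uniform
    scale: float = 1.0
    targets: ThermoTargets = field(default_factory=ThermoTargets)
    selection: Selection | None = None
    alternate_bonded: bool = True
    imc_frames: int = 20000
    seed: int = 0
    divergence_patience: int = 3

    @property
    def spec(self) -> MethodSpec:
        return parse_method(self.method)

    @property
    def onset_window(self) -> OnsetFitWindow:
        return OnsetFitWindow(self.onset_lower, self.onset_upper)

    @property
    def onset_policy(self) -> OnsetPolicy:
        return OnsetPolicy(self.imc_t1, self.imc_t2)


class ForwardModel(Protocol):
    """Anything that maps potentials to distributions.

    The surrogate solver implements this; an external-MD adapter would
    too (explicit extension point, not included).
    """

    composition: Composition
    omega: IntraMolecularMatrix

    def __call__(self, u: StackedField) -> StackedField: ...


@dataclass
class BondedTerm:
    """One bonded degree of freedom updated by distribution-IBI."""

    name: str
    target: Curve               # normalised target distribution
    potential: Curve            # current bonded potential
    model: Callable[[Curve], Curve]  # potential -> distribution


@dataclass
class IterationState:
    """State carried between iterations of the loop."""

    u: StackedField
    iteration: int = 0
    g: StackedField | None = None
    bonded: list[BondedTerm] = field(default_factory=list)
    cached_dcdh: np.ndarray | None = None
    cached_imc: ImcStats | None = None
    jacobian_builds: int = 0
    history: list[dict] = field(default_factory=list)

    def log(self, record: dict) -> None:
        self.history.append(record)


# ---------------------------------------------------------------------------
# initial guesses


def initial_guess(g_tgt: StackedField, method: str, composition: Composition,
                  omega: IntraMolecularMatrix, n_cut: int,
                  window: OnsetFitWindow | None = None,
                  cross: InteractionLabel | None = None) -> StackedField:
    """Starting potential: ``pmf`` (-kT ln g), ``hnc`` (closure inversion
    on the full RDF length), or ``avg`` ((u_AA + u_BB)/2 for one new
    cross interaction, others from the HNC guess)."""
    kT = composition.kT
    g_e = extrapolate_all(g_tgt, window)
    if method == "pmf":
        u = g_e.map(lambda v: -kT * np.log(np.maximum(v, 1e-300)),
                    kind="potential")
        return cut_and_shift(u, n_cut)
    if method in ("hnc", "avg"):
        c = direct_correlation(g_e.map(lambda v: v - 1.0, kind="correlation"),
                               omega, composition)
        u = hnc_guess(g_e, c, kT, n_cut=n_cut)
        if method == "hnc":
            return u
        if cross is None or cross.is_like:
            raise ValueError("the avg guess needs a cross interaction label")
        like_a = InteractionLabel(cross.a, cross.a)
        like_b = InteractionLabel(cross.b, cross.b)
        avg = 0.5 * (u[like_a].values + u[like_b].values)
        curves = [Curve(c.grid, avg.copy(), "potential") if l == cross else c
                  for l, c in zip(u.labels, u.curves)]
        return StackedField(list(u.labels), curves)
    raise ValueError(f"unknown initial guess method {method!r}")


# ---------------------------------------------------------------------------
# one iteration


def _apply_update(u: StackedField, du_flat: np.ndarray, index: StackIndex,
                  n_cut: int) -> StackedField:
    du = unflatten_bins(du_flat, index, u.grid)
    summed = StackedField(
        list(u.labels),
        [Curve(u.grid, u[l].values + du[l].values, "potential")
         for l in u.labels],
    )
    return cut_and_shift(summed, n_cut)


def _build_constraints(spec: MethodSpec, config: RunConfig,
                       g_k_e: StackedField, g_tgt_e: StackedField,
                       u: StackedField, J: np.ndarray,
                       composition: Composition,
                       col_index: StackIndex, row_index: StackIndex,
                       n_res: int) -> list[ConstraintRow]:
    rows: list[ConstraintRow] = []
    t = config.targets
    if spec.constrain_pressure:
        if t.pressure is None:
            raise ValueError("p- prefix given but no target pressure set")
        rows.append(pressure_constraint(g_k_e, u, composition, t.pressure,
                                        col_index))
    if spec.constrain_pe:
        if t.pe is None:
            raise ValueError("PE- prefix given but no target energy set")
        rows.append(pe_constraint(g_k_e, u, composition, t.pe, col_index))
    if spec.constrain_kbi:
        interactions = list(t.kbi) if t.kbi else None
        kbi_rows = kbi_constraint(g_k_e, g_tgt_e, J, row_index,
                                  interactions=interactions, n_res=n_res)
        if t.kbi:
            for row, label in zip(kbi_rows, t.kbi):
                row.rhs = kirkwood_buff(g_k_e[label], n_res) - t.kbi[label]
        rows.extend(kbi_rows)
    return rows


def run_iteration(state: IterationState, config: RunConfig,
                  forward: ForwardModel, g_tgt: StackedField) -> IterationState:
    """One pass of the loop; on forward-model failure the input state is
    preserved and the error re-raised."""
    spec = config.spec
    grid: RadialGrid = state.u.grid
    composition = forward.composition
    kT = composition.kT
    window = config.onset_window
    bonded_turn = (
        config.alternate_bonded and state.bonded and state.iteration % 2 == 1
    )

    g_k = forward(state.u)  # may raise; state untouched in that case
    g_tgt_e = extrapolate_all(g_tgt, window)
    g_k_e = extrapolate_all(g_k, window)

    m_cut = grid.n_cut - 1
    m_res = grid.n_res - 1
    col_index = StackIndex(tuple(state.u.labels), m_cut)
    row_index = StackIndex(tuple(state.u.labels), m_res)

    record = {
        "iteration": state.iteration,
        "phase": "bonded" if bonded_turn else "nonbonded",
        "chi_g": chi_g(g_k, g_tgt, n_max=grid.n_res + 1),
        "pressure": virial_pressure(g_k_e, state.u, composition),
        "pe": intermolecular_pe(g_k_e, state.u, composition),
        "kbi": {str(l): v for l, v in kirkwood_buff(g_k_e).items()},
    }

    new = IterationState(
        u=state.u, iteration=state.iteration + 1, g=g_k,
        bonded=list(state.bonded), cached_dcdh=state.cached_dcdh,
        cached_imc=state.cached_imc, jacobian_builds=state.jacobian_builds,
        history=list(state.history),
    )

    if bonded_turn:
        updated = []
        for term in state.bonded:
            dist = term.model(term.potential)
            du = kT * np.log(
                np.maximum(dist.values, 1e-300)
                / np.maximum(term.target.values, 1e-300)
            )
            du[term.target.values <= 0] = 0.0
            updated.append(replace(
                term,
                potential=Curve(term.potential.grid,
                                term.potential.values + du, "potential"),
            ))
        new.bonded = updated
        record["update"] = "distribution-ibi"
        new.log(record)
        return new

    if spec.base == "IBI":
        du = ibi_update(g_tgt_e, g_k_e, kT)
        du_flat = config.scale * flatten_bins(du, col_index)
        new.u = _apply_update(state.u, du_flat, col_index, grid.n_cut)
        record["update"] = "ibi"
        new.log(record)
        return new

    residual = flatten_bins(g_tgt_e, row_index) - flatten_bins(g_k_e, row_index)

    if spec.uses_hnc:
        if spec.one_time and state.cached_dcdh is not None:
            D = state.cached_dcdh
        else:
            source = g_tgt_e if spec.one_time else g_k_e
            h = source.map(lambda v: v - 1.0, kind="correlation")
            if spec.one_time and grid.n_points - 1 < 2 * grid.n_res:
                import warnings
                warnings.warn(
                    "one-time closure derivative computed from curves "
                    "shorter than twice the residuum range; truncation "
                    "artifacts possible", stacklevel=2,
                )
            D = dcdh_real(dcdh_k(h, forward.omega, composition), n_bins=m_res)
            new.cached_dcdh = D
            new.jacobian_builds += 1
        res_sq = StackIndex(tuple(state.u.labels), m_res)
        Jinv_full = jacobian_hnc(g_tgt_e, g_k_e, D, kT, res_sq)
        if spec.is_gauss_newton:
            J_full = np.linalg.inv(Jinv_full)
            J = _truncate_columns(J_full, res_sq, col_index)
        else:
            J = None
    else:  # IMC
        if spec.one_time and state.cached_imc is not None:
            stats = state.cached_imc
        else:
            sampler = getattr(forward, "imc_statistics", None)
            if sampler is None:
                raise ValueError(
                    "the forward model provides no pair-count statistics; "
                    "IMC methods need them"
                )
            u_for_stats = None if spec.one_time else state.u
            stats = sampler(u_for_stats, config.imc_frames,
                            config.seed + state.iteration)
            new.cached_imc = stats
            new.jacobian_builds += 1
        J_imc = jacobian_imc(stats, composition, grid)
        J_imc = improve_imc(J_imc, g_tgt_e, g_k_e, config.onset_policy, kT,
                            stats.index)
        if stats.index.n_bins != m_res:
            raise ValueError("IMC statistics were binned with a different "
                             "residuum range")
        if spec.is_gauss_newton:
            J = _truncate_columns(J_imc, stats.index, col_index)
        else:
            Jinv_full = np.linalg.inv(J_imc)
            J = None

    if spec.is_gauss_newton:
        if config.weighting == "default":
            weights = default_weights(g_tgt_e, row_index)
        elif config.weighting == "uniform":
            weights = None
        else:
            raise ValueError(f"unknown weighting {config.weighting!r}")
        constraints = _build_constraints(
            spec, config, g_k_e, g_tgt_e, state.u, J, composition,
            col_index, row_index, grid.n_res,
        )
        selection = config.selection or Selection.all(list(state.u.labels))
        J_red, res_red, w_red, cons_red, col_mask = selective_reduce(
            J, residual, selection, row_index, col_index, weights, constraints,
        )
        du_red = gauss_newton_step(J_red, res_red, weights=w_red,
                                   constraints=cons_red, scale=config.scale)
        du_flat = np.zeros(col_index.size)
        du_flat[col_mask] = du_red
        if cons_red:
            # the applied (scaled) update must satisfy the equally scaled
            # constraint right-hand side
            record["constraint_violation"] = float(max(
                abs(c.coeffs @ du_red - config.scale * c.rhs)
                for c in cons_red
            ))
    else:
        # Newton: square system on the cutoff range
        res_sq_idx = StackIndex(tuple(state.u.labels), m_res)
        Jinv_cut = _truncate_square(Jinv_full, res_sq_idx, col_index)
        res_cut = flatten_bins(g_tgt_e, col_index) - flatten_bins(g_k_e, col_index)
        du_flat = config.scale * newton_step(Jinv_cut, res_cut)

    new.u = _apply_update(state.u, du_flat, col_index, grid.n_cut)
    record["update"] = config.method
    record["max_du"] = float(np.max(np.abs(du_flat)))
    new.log(record)
    return new


def _truncate_columns(J: np.ndarray, row_index: StackIndex,
                      col_index: StackIndex) -> np.ndarray:
    """Keep all rows, but only the columns of potential bins <= n_cut."""
    cols = []
    for I in range(len(col_index.labels)):
        start = I * row_index.n_bins
        cols.append(J[:, start:start + col_index.n_bins])
    return np.concatenate(cols, axis=1)


def _truncate_square(M: np.ndarray, full_index: StackIndex,
                     cut_index: StackIndex) -> np.ndarray:
    """Square sub-block of a (du/dg) matrix on the cutoff range."""
    keep = np.zeros(full_index.size, dtype=bool)
    for label in cut_index.labels:
        start = full_index.labels.index(label) * full_index.n_bins
        keep[start:start + cut_index.n_bins] = True
    return M[np.ix_(keep, keep)]


# ---------------------------------------------------------------------------
# the loop


def run_loop(config: RunConfig, forward: ForwardModel, g_tgt: StackedField,
             u0: StackedField | None = None,
             bonded: Sequence[BondedTerm] = (),
             log_path=None) -> IterationState:
    """Run ``max_iterations`` passes from the configured initial guess.

    Aborts with :class:`DivergenceError` when chi(g) grows for
    ``divergence_patience`` consecutive iterations (consider scaling the
    update, e.g. ``scale=0.67``).
    """
    grid: RadialGrid = g_tgt.grid
    if u0 is None:
        u0 = initial_guess(g_tgt, config.initial_guess, forward.composition,
                           forward.omega, grid.n_cut, config.onset_window)
    state = IterationState(u=u0, bonded=list(bonded))
    worse = 0
    for _ in range(config.max_iterations):
        state = run_iteration(state, config, forward, g_tgt)
        if log_path is not None:
            with open(log_path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(state.history[-1]) + "\n")
        chis = [rec["chi_g"] for rec in state.history
                if rec["phase"] == "nonbonded"]
        # a genuine increase: ignore wiggles of a converged plateau
        if len(chis) >= 2 and chis[-1] > 1.001 * chis[-2] and chis[-1] > 1e-10:
            worse += 1
            if worse >= config.divergence_patience:
                raise DivergenceError(
                    f"chi(g) increased {worse} iterations in a row "
                    f"(last {chis[-1]:.3g}); consider scaling the update "
                    "(scale=0.67)"
                )
        else:
            worse = 0
    return state
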