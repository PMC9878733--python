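"""Newton / constrained Gauss-Newton updates and the thermodynamic
property evaluators (virial pressure, Kirkwood-Buff integrals,
intermolecular potential energy) with their constraint rows."""

import numpy as np
import pytest

from cginvert.grids import (
    Composition,
    Curve,
    RadialGrid,
    StackedField,
    InteractionLabel,
    interaction_labels,
)
from cginvert.jacobians import StackIndex, flatten_bins
from cginvert.updates import (
    ConstraintRow,
    Selection,
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


class TestNewtonStep:
    def test_zero_residual_gives_zero_update(self):
        rng = np.random.default_rng(0)
        J = rng.standard_normal((8, 8))
        assert not np.any(newton_step(J, np.zeros(8)))

    def test_exact_on_linear_forward_model(self):
        """One step reaches the target exactly when g is linear in u."""
        rng = np.random.default_rng(1)
        J = rng.standard_normal((10, 10)) + 5 * np.eye(10)
        u0 = rng.standard_normal(10)
        g0 = rng.standard_normal(10)
        g = lambda u: g0 + J @ (u - u0)
        g_tgt = rng.standard_normal(10)
        du = newton_step(np.linalg.inv(J), g_tgt - g(u0))
        assert np.allclose(g(u0 + du), g_tgt, atol=1e-10)

    def test_diagonal_low_density_reproduces_scalar_update(self):
        """du = -kT (g_tgt - g_k)/gbar, the a-Newton scalar formula."""
        kT, g_k, g_tgt = 1.7, 0.8, 1.1
        gbar = 0.5 * (g_k + g_tgt)
        Jinv = np.array([[-kT / gbar]])
        du = newton_step(Jinv, np.array([g_tgt - g_k]))
        assert du[0] == pytest.approx(-kT * (g_tgt - g_k) / gbar)
        # overshoot direction: g_k > g_tgt must raise the potential
        du2 = newton_step(Jinv, np.array([-(0.3)]))
        assert du2[0] > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            newton_step(np.eye(3), np.zeros(4))


class TestGaussNewtonStep:
    def test_square_unweighted_equals_newton(self):
        rng = np.random.default_rng(2)
        J = rng.standard_normal((12, 12)) + 4 * np.eye(12)
        res = rng.standard_normal(12)
        du_gn = gauss_newton_step(J, res)
        du_n = newton_step(np.linalg.inv(J), res)
        assert np.max(np.abs(du_gn - du_n)) < 1e-10

    def test_constraints_feasible_to_tolerance(self):
        rng = np.random.default_rng(3)
        J = rng.standard_normal((20, 10))
        res = rng.standard_normal(20)
        cons = [
            ConstraintRow(rng.standard_normal(10), 0.7, "pressure"),
            ConstraintRow(rng.standard_normal(10), -1.2, "kbi:A-A"),
        ]
        du = gauss_newton_step(J, res, constraints=cons)
        for c in cons:
            assert abs(c.coeffs @ du - c.rhs) < 1e-10

    def test_matches_lagrange_multiplier_oracle(self):
        """6-point equality-constrained least squares against the
        brute-force KKT (Lagrange-multiplier) system."""
        rng = np.random.default_rng(4)
        J = rng.standard_normal((6, 6))
        W = np.diag(rng.random(6) + 0.5)
        res = rng.standard_normal(6)
        K = rng.standard_normal((2, 6))
        d = rng.standard_normal(2)
        cons = [ConstraintRow(K[0], d[0], "c0"), ConstraintRow(K[1], d[1], "c1")]
        du = gauss_newton_step(J, res, weights=np.diag(W), constraints=cons)
        # KKT: [A^T A  K^T; K  0] [du; lam] = [A^T b; d]
        A = W @ J
        b = W @ res
        kkt = np.block([[A.T @ A, K.T], [K, np.zeros((2, 2))]])
        rhs = np.concatenate([A.T @ b, d])
        oracle = np.linalg.solve(kkt, rhs)[:6]
        assert np.max(np.abs(du - oracle)) < 1e-8

    def test_scale_multiplies_update(self):
        rng = np.random.default_rng(5)
        J = rng.standard_normal((8, 8)) + 3 * np.eye(8)
        res = rng.standard_normal(8)
        assert np.allclose(gauss_newton_step(J, res, scale=0.67),
                           0.67 * gauss_newton_step(J, res))

    def test_rank_deficient_constraints_rejected(self):
        J = np.eye(4)
        res = np.ones(4)
        row = np.array([1.0, 0, 0, 0])
        cons = [ConstraintRow(row, 0.0, "a"), ConstraintRow(row, 1.0, "b")]
        with pytest.raises(ValueError, match="rank deficient"):
            gauss_newton_step(J, res, constraints=cons)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            gauss_newton_step(np.eye(3), np.ones(3), weights=np.array([1, -1, 1.0]))


class TestSelectiveReduce:
    def setup_system(self):
        labels = tuple(interaction_labels(["A", "B"]))
        row_idx = StackIndex(labels, 5)
        col_idx = StackIndex(labels, 3)
        rng = np.random.default_rng(6)
        J = rng.standard_normal((row_idx.size, col_idx.size))
        res = rng.standard_normal(row_idx.size)
        return labels, row_idx, col_idx, J, res

    def test_full_selection_is_identity(self):
        labels, ri, ci, J, res = self.setup_system()
        sel = Selection.all(labels)
        J2, res2, _, _, mask = selective_reduce(J, res, sel, ri, ci)
        assert np.array_equal(J2, J)
        assert np.array_equal(res2, res)
        assert mask.all()

    def test_single_interaction_shapes(self):
        """Only the cross interaction active: columns of u_AB, rows of
        g_AB (the mixture workflow)."""
        labels, ri, ci, J, res = self.setup_system()
        ab = InteractionLabel("A", "B")
        sel = Selection(update=frozenset({ab}), target=frozenset({ab}))
        J2, res2, _, _, mask = selective_reduce(J, res, sel, ri, ci)
        assert J2.shape == (5, 3)
        assert mask.sum() == 3

    def test_reduced_solution_matches_pinned_oracle(self):
        """Solving the reduced system equals solving the full system with
        the frozen potentials pinned to zero update."""
        labels, ri, ci, J, res = self.setup_system()
        ab = InteractionLabel("A", "B")
        sel = Selection(update=frozenset({ab}), target=frozenset(labels))
        J2, res2, _, _, mask = selective_reduce(J, res, sel, ri, ci)
        du_red = gauss_newton_step(J2, res2)
        # oracle: full least squares over the active columns only
        oracle = np.linalg.lstsq(J[:, mask], res, rcond=None)[0]
        assert np.allclose(du_red, oracle, atol=1e-10)

    def test_empty_selection_rejected(self):
        labels, *_ = self.setup_system()
        with pytest.raises(ValueError):
            Selection(update=frozenset(), target=frozenset(labels))


@pytest.fixture
def thermo_system():
    grid = RadialGrid(n_points=128, dr=0.02, n_cut=100, n_res=120)
    comp = Composition(counts={"A": 200, "B": 100}, volume=60.0,
                       temperature=250.0)
    labels = interaction_labels(["A", "B"])
    rng = np.random.default_rng(7)
    g_curves, u_curves = [], []
    for i, _ in enumerate(labels):
        onset = 0.5 * (1 + np.tanh((grid.r - 0.3) / 0.05))
        gv = onset * (1.0 + 0.4 * np.exp(-grid.r) * np.cos(5 * grid.r + i))
        uv = 0.8 * np.exp(-((grid.r - 0.35) / 0.2) ** 2) - 0.3 * np.exp(
            -((grid.r - 0.6) / 0.3) ** 2)
        uv = uv - uv[grid.n_cut]
        uv[grid.n_cut:] = 0.0
        g_curves.append(Curve(grid, np.clip(gv, 0, None), "rdf"))
        u_curves.append(Curve(grid, uv, "potential"))
    return (grid, comp, labels,
            StackedField(labels, g_curves), StackedField(labels, u_curves))


class TestVirialPressure:
    def test_ideal_gas_limit(self, thermo_system):
        grid, comp, labels, g, u = thermo_system
        u0 = u.map(lambda v: np.zeros_like(v), kind="potential")
        from cginvert.grids import PRESSURE_TO_BAR
        expected = comp.total_density * comp.kT * PRESSURE_TO_BAR
        assert virial_pressure(g, u0, comp) == pytest.approx(expected)

    def test_single_force_bin_by_hand(self):
        """A potential that is nonzero in one bin contributes two midpoint
        force terms; the discrete sum is evaluated by hand."""
        grid = RadialGrid(n_points=16, dr=0.1, n_cut=12)
        comp = Composition(counts={"A": 50}, volume=20.0, temperature=300.0)
        labels = interaction_labels(["A"])
        g = StackedField(labels, [Curve(grid, np.ones(16), "rdf")])
        uv = np.zeros(16)
        j = 6
        uv[j] = 0.5
        u = StackedField(labels, [Curve(grid, uv, "potential")])
        rho = 2.5
        rm = grid.midpoints
        # force (du/dr) is +0.5/dr at midpoint j-1 and -0.5/dr at j
        hand = -(2 * np.pi / 3) * 1.0 * rho * rho * (
            rm[j - 1] ** 3 * (0.5 / grid.dr) + rm[j] ** 3 * (-0.5 / grid.dr)
        ) * grid.dr
        from cginvert.grids import PRESSURE_TO_BAR
        expected = (rho * comp.kT + hand) * PRESSURE_TO_BAR
        assert virial_pressure(g, u, comp) == pytest.approx(expected, rel=1e-12)

    def test_species_split_invariance(self, thermo_system):
        """Splitting one species into two identical half-populations
        leaves the pressure unchanged (2 - delta bookkeeping)."""
        grid, comp, labels, g, u = thermo_system
        p0 = virial_pressure(g, u, comp)
        comp2 = Composition(counts={"A1": 100, "A2": 100, "B": 100},
                            volume=60.0, temperature=250.0)
        labels2 = interaction_labels(["A1", "A2", "B"])
        remap = {("A1", "A1"): "A-A", ("A1", "A2"): "A-A", ("A2", "A2"): "A-A",
                 ("A1", "B"): "A-B", ("A2", "B"): "A-B", ("B", "B"): "B-B"}
        g2 = StackedField(labels2, [g[remap[(l.a, l.b)]].copy() for l in labels2])
        u2 = StackedField(labels2, [u[remap[(l.a, l.b)]].copy() for l in labels2])
        assert virial_pressure(g2, u2, comp2) == pytest.approx(p0, rel=1e-12)


class TestKirkwoodBuff:
    def test_ideal_rdf_gives_zero(self, small_grid):
        g = Curve(small_grid, np.ones(64), "rdf")
        assert kirkwood_buff(g, n_res=60) == pytest.approx(0.0)

    def test_step_rdf_matches_direct_sum(self, small_grid):
        a = 0.6
        gv = (small_grid.r >= a).astype(float)
        g = Curve(small_grid, gv, "rdf")
        got = kirkwood_buff(g, n_res=60)
        r = small_grid.r[:60]
        direct = float(np.sum(4 * np.pi * r ** 2 * (gv[:60] - 1)) * small_grid.dr)
        assert got == pytest.approx(direct, rel=1e-14)
        # continuum value: the left-endpoint sum sees the sharp edge half
        # a bin early, so compare against the half-bin-shifted sphere
        a_eff = a - small_grid.dr / 2
        assert got == pytest.approx(-(4 * np.pi / 3) * a_eff ** 3, abs=0.02)

    def test_richardson_convergence(self):
        """Halving dr reduces the quadrature error by about four."""
        a = 0.37
        exact = -(4 * np.pi / 3) * a ** 3
        errs = []
        for n, dr in ((200, 0.01), (400, 0.005)):
            grid = RadialGrid(n_points=n, dr=dr)
            gv = np.clip((grid.r - a) / dr + 0.5, 0, 1)  # linear edge
            g = Curve(grid, gv, "rdf")
            errs.append(abs(kirkwood_buff(g, n_res=n - 1) - exact))
        assert errs[1] < errs[0] / 3.0


class TestIntermolecularPe:
    def test_zero_potential_gives_zero(self, thermo_system):
        grid, comp, labels, g, u = thermo_system
        u0 = u.map(lambda v: np.zeros_like(v), kind="potential")
        assert intermolecular_pe(g, u0, comp) == 0.0

    def test_single_bin_by_hand(self):
        grid = RadialGrid(n_points=16, dr=0.1, n_cut=12)
        comp = Composition(counts={"A": 50}, volume=20.0, temperature=300.0)
        labels = interaction_labels(["A"])
        g = StackedField(labels, [Curve(grid, np.ones(16), "rdf")])
        uv = np.zeros(16)
        uv[4] = -0.7
        u = StackedField(labels, [Curve(grid, uv, "potential")])
        hand = 0.5 * (50 * 50 / 20.0) * 4 * np.pi * grid.r[4] ** 2 * (-0.7) \
            * grid.dr / 50
        assert intermolecular_pe(g, u, comp) == pytest.approx(hand, rel=1e-12)

    def test_intensive_under_system_doubling(self, thermo_system):
        grid, comp, labels, g, u = thermo_system
        pe1 = intermolecular_pe(g, u, comp)
        comp2 = Composition(counts={"A": 400, "B": 200}, volume=120.0,
                            temperature=250.0)
        assert intermolecular_pe(g, u, comp2) == pytest.approx(pe1, rel=1e-12)


class TestConstraintRows:
    def test_pressure_row_zero_rhs_at_target(self, thermo_system):
        grid, comp, labels, g, u = thermo_system
        idx = StackIndex(tuple(labels), grid.n_cut - 1)
        p_now = virial_pressure(g, u, comp, n_cut=grid.n_cut)
        row = pressure_constraint(g, u, comp, p_now, idx)
        assert row.rhs == pytest.approx(0.0, abs=1e-9)

    def test_pressure_coefficients_match_finite_differences(self, thermo_system):
        """The pressure is linear in u at fixed g, so the analytic row
        equals central differences essentially exactly.  The row stores
        -dp/du (sign convention K du = d with d = p_k - p_tgt)."""
        grid, comp, labels, g, u = thermo_system
        idx = StackIndex(tuple(labels), grid.n_cut - 1)
        row = pressure_constraint(g, u, comp, 0.0, idx)
        eps = 1e-2  # p is linear in u: a large step has no truncation error
        for label in labels:
            for j in (5, 40, grid.n_cut - 1):
                up = u.map(lambda v: v.copy(), kind="potential")
                um = u.map(lambda v: v.copy(), kind="potential")
                up[label].values[j] += eps
                um[label].values[j] -= eps
                fd = (virial_pressure(g, up, comp, n_cut=grid.n_cut)
                      - virial_pressure(g, um, comp, n_cut=grid.n_cut)) / (2 * eps)
                assert row.coeffs[idx.flat(label, j)] == pytest.approx(
                    -fd, rel=1e-6, abs=1e-12)

    def test_pressure_coefficients_scale_with_pair_counts(self, thermo_system):
        """Row entries for interaction ab carry the rho_a rho_b (2 - delta)
        prefactor; recomputed from scratch after doubling N_B."""
        grid, comp, labels, g, u = thermo_system
        idx = StackIndex(tuple(labels), grid.n_cut - 1)
        row1 = pressure_constraint(g, u, comp, 0.0, idx)
        comp2 = Composition(counts={"A": 200, "B": 200}, volume=60.0,
                            temperature=250.0)
        row2 = pressure_constraint(g, u, comp2, 0.0, idx)
        bb = idx.block(InteractionLabel("B", "B"))
        ab = idx.block(InteractionLabel("A", "B"))
        aa = idx.block(InteractionLabel("A", "A"))
        assert np.allclose(row2.coeffs[bb], 4.0 * row1.coeffs[bb])
        assert np.allclose(row2.coeffs[ab], 2.0 * row1.coeffs[ab])
        assert np.allclose(row2.coeffs[aa], row1.coeffs[aa])

    def test_kbi_row_zero_rhs_at_target(self, thermo_system):
        grid, comp, labels, g, u = thermo_system
        ri = StackIndex(tuple(labels), grid.n_res - 1)
        J = np.zeros((ri.size, ri.size))
        rows = kbi_constraint(g, g, J, ri, n_res=grid.n_res)
        assert len(rows) == len(labels)   # one row per interaction
        for row in rows:
            assert row.rhs == pytest.approx(0.0, abs=1e-12)

    def test_kbi_constrained_step_exact_on_linear_model(self, thermo_system):
        """On a forward model that is exactly linear, one constrained
        step reaches the target KBI exactly."""
        grid, comp, labels, g, u = thermo_system
        ri = StackIndex(tuple(labels), grid.n_res - 1)
        rng = np.random.default_rng(8)
        J = rng.standard_normal((ri.size, ri.size)) * 0.05 - np.eye(ri.size)
        g_flat = flatten_bins(g, ri)
        g_lin = lambda du: g_flat + J @ du
        target_label = labels[0]
        g_tgt_stack = g.map(lambda v: np.clip(v * 1.02, 0, None), kind="rdf")
        rows = kbi_constraint(g, g_tgt_stack, J, ri, n_res=grid.n_res)
        res = flatten_bins(g_tgt_stack, ri) - g_flat
        du = gauss_newton_step(J, res, constraints=rows)
        g_new = g_lin(du)
        r = grid.r[1:ri.n_bins + 1]
        w = 4 * np.pi * r ** 2 * grid.dr
        w[r >= grid.n_res * grid.dr] = 0.0
        for label in labels:
            sl = ri.block(label)
            G_new = float(w @ (g_new[sl] - 1.0))
            G_tgt = kirkwood_buff(g_tgt_stack[label], grid.n_res)
            assert G_new == pytest.approx(G_tgt, abs=1e-10)

    def test_pe_row_matches_finite_differences(self, thermo_system):
        grid, comp, labels, g, u = thermo_system
        idx = StackIndex(tuple(labels), grid.n_cut - 1)
        row = pe_constraint(g, u, comp, 0.0, idx)
        eps = 1e-5
        label = labels[1]
        for j in (10, 60):
            up = u.map(lambda v: v.copy(), kind="potential")
            um = u.map(lambda v: v.copy(), kind="potential")
            up[label].values[j] += eps
            um[label].values[j] -= eps
            fd = (intermolecular_pe(g, up, comp, n_cut=grid.n_cut)
                  - intermolecular_pe(g, um, comp, n_cut=grid.n_cut)) / (2 * eps)
            assert row.coeffs[idx.flat(label, j)] == pytest.approx(
                -fd, rel=1e-6)

    def test_pe_row_intensive(self, thermo_system):
        grid, comp, labels, g, u = thermo_system
        idx = StackIndex(tuple(labels), grid.n_cut - 1)
        row1 = pe_constraint(g, u, comp, 0.0, idx)
        comp2 = Composition(counts={"A": 400, "B": 200}, volume=120.0,
                            temperature=250.0)
        row2 = pe_constraint(g, u, comp2, 0.0, idx)
        assert np.allclose(row2.coeffs, row1.coeffs)
        assert row2.rhs == pytest.approx(row1.rhs)

    def test_unknown_kbi_interaction_rejected(self, thermo_system):
        grid, comp, labels, g, u = thermo_system
        ri = StackIndex(tuple(labels), grid.n_res - 1)
        with pytest.raises(ValueError, match="not present"):
            kbi_constraint(g, g, np.zeros((ri.size, ri.size)), ri,
                           interactions=[InteractionLabel("A", "C")])


class TestDefaultWeights:
    def test_formula(self, thermo_system):
        grid, comp, labels, g, u = thermo_system
        idx = StackIndex(tuple(labels), grid.n_res - 1)
        w = default_weights(g, idx)
        gt = flatten_bins(g, idx)
        r = np.tile(grid.r[1:idx.n_bins + 1], len(labels))
        assert np.allclose(w, r ** 2 / (gt + 1e-30))
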