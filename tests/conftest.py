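"""Shared fixtures: small grids and solved toy systems (session scoped —
the structure solves are the expensive part of the suite)."""

import numpy as np
import pytest

from cginvert.grids import (
    Composition,
    Curve,
    RadialGrid,
    StackedField,
    interaction_labels,
)
from cginvert.rism import MoleculeGraph, build_omega
from cginvert.surrogate import SolverSettings, solve_structure, toy_systems


@pytest.fixture(scope="session")
def toys():
    return toy_systems()


@pytest.fixture(scope="session")
def lj_solution(toys):
    """Solved single-bead LJ fluid: (system, g, c)."""
    s = toys["lj_fluid"]
    g, c = s.solve(return_c=True)
    return s, g, c


@pytest.fixture(scope="session")
def trimer_solution(toys):
    s = toys["trimer"]
    g, c = s.solve(return_c=True)
    return s, g, c


@pytest.fixture(scope="session")
def soft_fluid():
    """Single-bead fluid with a soft Gaussian-core potential on a 64-point
    grid; its RDF is positive everywhere, so derivative oracles need no
    onset handling."""
    grid = RadialGrid.from_lengths(dr=0.05, r_max=3.2, r_cut=3.0)
    comp = Composition(counts={"A": 640}, volume=1280.0, temperature=120.27)
    mol = MoleculeGraph(sites=["A"])
    omega = build_omega(mol, grid.k_grid())
    labels = interaction_labels(["A"])
    u = StackedField(
        labels,
        [Curve(grid, 2.0 * comp.kT * np.exp(-(grid.r / 0.4) ** 2), "potential")],
    )
    settings = SolverSettings(tolerance=1e-12)
    g = solve_structure(u, comp, omega, settings)
    return {
        "grid": grid, "composition": comp, "omega": omega, "labels": labels,
        "u": u, "g": g, "settings": settings, "molecule": mol,
    }


@pytest.fixture
def small_grid():
    return RadialGrid(n_points=64, dr=0.05)
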