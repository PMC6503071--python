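"""Shared fixtures: analytic tube geometry, steady plasma flow, and the
paired RBC/plasma tube run reused by the flow-physics and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from redwall.config import GeometryConfig, RunConfig, run_pair
from redwall.geometry import make_tube, signed_distance, sinusoidal_bend
from redwall.solver import BoundaryCondition, StokesSolver, classify_grid

# Desk-scale study conditions for the cell-laden tube fixture: a 10 µm
# capillary-sized tube, 24 µm periodic segment, 0.5 µm grid, feed
# hematocrit 0.2, matched inlet flow rate 2.5e-14 m³/s (mean velocity
# ~0.3 mm/s), 10 ms horizon sampled every 0.5 ms.
TUBE_D = 10.0
TUBE_L = 24.0
GRID_H = 0.5
PAIR_HT = 0.2
PAIR_Q = 2.5e-14
PAIR_T_END = 0.01
PAIR_SEED = 1


@pytest.fixture(scope="session")
def tube_geometry():
    mesh, spec = make_tube(TUBE_D, TUBE_L, None, 0.5)
    df = signed_distance(mesh, GRID_H, min_diameter=TUBE_D)
    half = TUBE_D / 2 + 1.0
    grid = classify_grid(df, GRID_H, lo=np.array([0.0, -half, -half]),
                         hi=np.array([TUBE_L, half, half]), periodic_x=True)
    return mesh, spec, df, grid


@pytest.fixture(scope="session")
def poiseuille_steady(tube_geometry):
    """Plasma-only pressure-driven steady state, G = 0.1 Pa/µm."""
    _, _, _, grid = tube_geometry
    sol = StokesSolver(grid, BoundaryCondition("pressure_drop", 0.1))
    state = sol.run_to_steady(sol.initial_state(), 2e-5, tol=1e-9,
                              max_steps=2500)
    return sol, state


@pytest.fixture(scope="session")
def curved_tube_steady():
    """Plasma-only steady flow in a sinusoidally bent tube."""
    D, L, amp = 8.0, 48.0, 3.0
    mesh, spec = make_tube(D, L, sinusoidal_bend(amp, 1.0), 0.4)
    df = signed_distance(mesh, 0.5, min_diameter=D)
    half = D / 2 + amp + 1.0
    grid = classify_grid(df, 0.5, lo=np.array([0.0, -half, -half + amp]),
                         hi=np.array([L, half, half - amp]), periodic_x=True)
    sol = StokesSolver(grid, BoundaryCondition("pressure_drop", 0.1))
    state = sol.run_to_steady(sol.initial_state(), 2e-5, tol=1e-8,
                              max_steps=2000)
    return mesh, spec, grid, sol, state


@pytest.fixture(scope="session")
def rbc_pair():
    """Paired RBC / plasma-only tube runs at matched inlet flow rate."""
    cfg = RunConfig(
        geometry=GeometryConfig(kind="tube", diameter=TUBE_D, length=TUBE_L),
        bc_kind="inlet_flow_rate", bc_value=PAIR_Q, hematocrit=PAIR_HT,
        seed=PAIR_SEED, t_end=PAIR_T_END, h=GRID_H)
    res_rbc, res_pl, rep = run_pair(cfg)
    assert res_rbc.status == "ok", res_rbc.status
    assert res_pl.status == "ok", res_pl.status
    return cfg, res_rbc, res_pl, rep
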