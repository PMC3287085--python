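"""Shared fixtures.

The expensive solves (full default four-arm study, channel validation
fixtures) are session-scoped and reused across test modules.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

import coroflow as cf
from coroflow.pipeline import default_config, run_study
from coroflow.solver import NavierStokesSolver, SolverConfig


@pytest.fixture(scope="session")
def vessel_spec():
    return cf.VesselSpec()


@pytest.fixture(scope="session")
def plain_outline(vessel_spec):
    return cf.build_bifurcation(vessel_spec)


@pytest.fixture(scope="session")
def plaqued_outline(plain_outline):
    out = plain_outline
    for p in cf.default_plaques():
        out = cf.apply_plaque(out, p)
    return out


@pytest.fixture(scope="session")
def plaque_mesh(plaqued_outline):
    return cf.generate_mesh(plaqued_outline, 0.25, seed=0)


# ---------------------------------------------------------------------------
# channel flow fixtures (solver validation oracles)

CHANNEL = {"height_mm": 4.0, "length_mm": 12.0, "h_mm": 0.15,
           "rho": 1060.0, "mu": 0.0035, "force_pa_per_m": 70.0}


@pytest.fixture(scope="session")
def poiseuille():
    """Steady body-force-driven channel flow, solved to tight residual."""
    c = CHANNEL
    mesh = cf.channel_mesh(c["length_mm"], c["height_mm"], c["h_mm"], seed=1)
    G, rho, mu = c["force_pa_per_m"], c["rho"], c["mu"]
    H = c["height_mm"] * 1e-3
    cfg = SolverConfig(dt=2.0, steps_per_cycle=8, cycles=1,
                       residual_target=1e-9, rho=rho)
    solver = NavierStokesSolver(
        mesh, cfg, rheology=cf.NewtonianModel(mu=mu, rho=rho),
        waveform=None, body_force=lambda t: (G / rho, 0.0),
        u_ref=G * (H / 2) ** 2 / (2 * mu), d_ref=H)
    t0 = time.perf_counter()
    state = solver.initialize()
    for _ in range(6):
        state = solver.advance(state)
    elapsed = time.perf_counter() - t0
    return {"mesh": mesh, "solver": solver, "state": state,
            "elapsed_s": elapsed, **c}


@pytest.fixture(scope="session")
def womersley():
    """Oscillatory body-force-driven channel flow (one start-up cycle
    discarded), with its analytic complex amplitude."""
    rho, mu = 1060.0, 0.0035
    H, L, h = 2.0, 6.0, 0.15
    G, om = 70.0, 2.0 * np.pi
    mesh = cf.channel_mesh(L, H, h, seed=1)
    cfg = SolverConfig(dt=0.0125, steps_per_cycle=80, cycles=2,
                       residual_target=1e-6, rho=rho)
    a = H * 1e-3 / 2
    solver = NavierStokesSolver(
        mesh, cfg, rheology=cf.NewtonianModel(mu=mu, rho=rho),
        waveform=None,
        body_force=lambda t: (G * np.cos(om * t) / rho, 0.0),
        u_ref=G * a ** 2 / (2 * mu), d_ref=H * 1e-3)
    t0 = time.perf_counter()
    result = solver.run_cycles()
    elapsed = time.perf_counter() - t0
    nu = mu / rho
    k = np.sqrt(1j * om / nu)
    exact_amp = (G / (1j * rho * om)) * (1.0 - 1.0 / np.cosh(k * a))
    return {"mesh": mesh, "solver": solver, "result": result,
            "omega": om, "exact_centerline_amplitude": exact_amp,
            "center": np.array([[L / 2, H / 2]]), "elapsed_s": elapsed}


# ---------------------------------------------------------------------------
# the full default study (shared by the acceptance tests)


@pytest.fixture(scope="session")
def full_study():
    cfg = default_config()
    t0 = time.perf_counter()
    result = run_study(cfg)
    result.wall_elapsed_s = time.perf_counter() - t0
    return result
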