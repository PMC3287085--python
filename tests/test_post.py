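"""Post-processing: PSG recovery, WSS, section sampling, summaries."""

import numpy as np
import pytest

import coroflow as cf
from coroflow.geometry import SectionPlane
from coroflow.meshing import Mesh
from coroflow.post import (SectionProfile, SummaryReport,
                           recirculation_fraction, sample_section, summarize,
                           wall_shear_stress)
from coroflow.solver import FlowState

MM = 1e-3


def _state_with_pressure(mesh, p):
    z = np.zeros(mesh.n_nodes)
    return FlowState(time=0.0, ux=z.copy(), uy=z.copy(), p=p,
                     viscosity=np.full(mesh.n_nodes, 0.0035))


@pytest.fixture(scope="module")
def channel():
    return cf.channel_mesh(8.0, 4.0, 0.25, seed=0)


class TestPressureGradientMagnitude:
    def test_uniform_pressure_gives_zero(self, channel):
        state = _state_with_pressure(channel, np.full(channel.n_nodes, 7.0))
        assert np.abs(cf.pressure_gradient_magnitude(state, channel)).max() \
            < 1e-9

    def test_linear_field_exact(self, channel):
        x = channel.points[:, 0] * MM
        state = _state_with_pressure(channel, 100.0 * x)
        psg = cf.pressure_gradient_magnitude(state, channel)
        np.testing.assert_allclose(psg, 100.0, rtol=1e-9)

    def test_quadratic_field_matches_fd_oracle(self, channel):
        x = channel.points[:, 0] * MM
        y = channel.points[:, 1] * MM
        state = _state_with_pressure(channel, x ** 2 + 3.0 * y)
        psg = cf.pressure_gradient_magnitude(state, channel)
        # central finite differences of p = x^2 + 3y give (2x, 3)
        eps = 1e-6
        gx = ((x + eps) ** 2 - (x - eps) ** 2) / (2 * eps)
        oracle = np.hypot(gx, 3.0)
        interior = ((channel.points[:, 0] > 0.5)
                    & (channel.points[:, 0] < 7.5)
                    & (channel.points[:, 1] > 0.5)
                    & (channel.points[:, 1] < 3.5))
        err = np.abs(psg - oracle)[interior] / oracle[interior]
        assert err.max() < 0.01

    def test_rotation_equivariance(self, channel):
        th = np.deg2rad(33.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = Mesh(points=channel.points @ R.T,
                       triangles=channel.triangles,
                       boundary_edges=channel.boundary_edges,
                       boundary_tags=channel.boundary_tags, h=channel.h)
        x = channel.points[:, 0] * MM
        y = channel.points[:, 1] * MM
        p = x ** 2 + 3.0 * y
        psg0 = cf.pressure_gradient_magnitude(
            _state_with_pressure(channel, p), channel)
        psg1 = cf.pressure_gradient_magnitude(
            _state_with_pressure(rotated, p), rotated)
        np.testing.assert_allclose(psg1, psg0, rtol=1e-10, atol=1e-12)


class TestWallShearStress:
    def test_poiseuille_closed_form(self, poiseuille):
        # WSS = G*H/2 (equivalently 6 mu U_mean / H)
        mesh, state = poiseuille["mesh"], poiseuille["state"]
        G = poiseuille["force_pa_per_m"]
        H = poiseuille["height_mm"] * 1e-3
        wall = wall_shear_stress(state, mesh,
                                 cf.NewtonianModel(mu=poiseuille["mu"]))
        x = wall.points[:, 0]
        interior = (x > 1.0) & (x < poiseuille["length_mm"] - 1.0)
        exact = G * H / 2.0
        assert np.nanmax(np.abs(wall.wss[interior] - exact)) / exact < 0.05

    def test_zero_flow_gives_zero_wss(self, poiseuille):
        mesh = poiseuille["mesh"]
        state = _state_with_pressure(mesh, np.zeros(mesh.n_nodes))
        wall = wall_shear_stress(state, mesh, cf.NewtonianModel())
        assert np.nanmax(wall.wss) == 0.0

    def test_opposite_walls_symmetric(self, poiseuille):
        mesh, state = poiseuille["mesh"], poiseuille["state"]
        wall = wall_shear_stress(state, mesh, cf.NewtonianModel())
        x, y = wall.points[:, 0], wall.points[:, 1]
        interior = (x > 1.0) & (x < poiseuille["length_mm"] - 1.0)
        H = poiseuille["height_mm"]
        bottom = np.nanmean(wall.wss[interior & (y < H / 2)])
        top = np.nanmean(wall.wss[interior & (y > H / 2)])
        assert abs(top - bottom) / bottom < 0.01


@pytest.fixture(scope="module")
def midplane(poiseuille):
    L, H = poiseuille["length_mm"], poiseuille["height_mm"]
    return SectionPlane(label="mid", branch="LMS", s=L / 2,
                        start=np.array([L / 2, 1e-6]),
                        end=np.array([L / 2, H - 1e-6]),
                        streamwise=np.array([1.0, 0.0]))


class TestSampleSection:
    def test_noslip_endpoints(self, poiseuille, midplane):
        prof = sample_section(poiseuille["state"], poiseuille["mesh"],
                              midplane)
        peak = np.abs(prof.streamwise).max()
        assert abs(prof.streamwise[0]) < 1e-3 * peak
        assert abs(prof.streamwise[-1]) < 1e-3 * peak

    def test_parabolic_peak_to_mean_ratio(self, poiseuille, midplane):
        prof = sample_section(poiseuille["state"], poiseuille["mesh"],
                              midplane, n=201)
        ratio = prof.streamwise.max() / prof.mean_streamwise()
        assert ratio == pytest.approx(1.5, rel=0.02)

    def test_section_flux_matches_boundary_flux(self, poiseuille, midplane):
        prof = sample_section(poiseuille["state"], poiseuille["mesh"],
                              midplane, n=201)
        q_out = poiseuille["solver"].boundary_flux(poiseuille["state"],
                                                   "outlet_lad")
        assert prof.flux() == pytest.approx(q_out, rel=0.01)

    def test_outside_plane_rejected(self, poiseuille):
        plane = SectionPlane(label="x", branch="LMS", s=0.0,
                             start=np.array([-5.0, 0.0]),
                             end=np.array([-5.0, 4.0]),
                             streamwise=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="outside"):
            sample_section(poiseuille["state"], poiseuille["mesh"], plane)


class TestRecirculationFraction:
    def _profile(self, streamwise):
        n = len(streamwise)
        return SectionProfile(label="t", branch="LAD",
                              positions=np.linspace(0, 1, n),
                              streamwise=np.asarray(streamwise, dtype=float),
                              transverse=np.zeros(n), width=1.0)

    def test_poiseuille_profile_has_none(self):
        xi = np.linspace(0.0, 1.0, 51)
        assert recirculation_fraction(self._profile(6 * xi * (1 - xi))) == 0.0

    def test_half_negated_profile(self):
        xi = np.linspace(0.0, 1.0, 50)
        v = 6 * xi * (1 - xi) + 1e-12
        v[:25] *= -1.0
        assert recirculation_fraction(self._profile(v)) == pytest.approx(
            0.5, abs=1.0 / 50)


@pytest.fixture(scope="module")
def zero_flow_arms():
    """Two study arms solved with a zero inflow waveform."""
    from coroflow.inflow import Waveform
    from coroflow.pipeline import _reference_planes
    from coroflow.post import ArmResult
    from coroflow.solver import NavierStokesSolver, SolverConfig

    spec = cf.VesselSpec()
    plain = cf.build_bifurcation(spec)
    plaques = cf.default_plaques()
    plaqued = plain
    for p in plaques:
        plaqued = cf.apply_plaque(plaqued, p)
    zero = Waveform(period=1.0, a0=0.0, a=np.zeros(1), b=np.zeros(1))
    cfg = SolverConfig(dt=0.1, steps_per_cycle=10, cycles=1)
    arms = {}
    for name, outline in (("newtonian_plaque", plaqued),
                          ("newtonian_noplaque", plain)):
        mesh = cf.generate_mesh(outline, 0.4, seed=0)
        solver = NavierStokesSolver(mesh, cfg,
                                    rheology=cf.NewtonianModel(),
                                    waveform=zero)
        res = solver.run_cycles()
        arms[name] = ArmResult(
            name=name, rheology_name="newtonian",
            plaque=name.endswith("_plaque"),
            rheology=cf.NewtonianModel(), solver=solver, result=res,
            outline=outline,
            sections=cf.define_sections(outline, plaques=plaques),
            reference_sections=_reference_planes(outline, plaques))
    return arms, plaques

class TestSummarize:
    def test_missing_arm_rejected(self, zero_flow_arms):
        arms, plaques = zero_flow_arms
        with pytest.raises(ValueError, match="missing"):
            summarize(arms, plaques, times=(0.4, 0.7))

    def test_zero_fields_give_zero_ranges(self, zero_flow_arms):
        arms, plaques = zero_flow_arms
        rep = summarize(arms, plaques, times=(0.4, 0.7), require_all=False)
        for arm in rep.arms.values():
            for tk in ("0.4", "0.7"):
                for rng in arm[tk]["velocity_mm_s"].values():
                    assert rng == {"min": 0.0, "max": 0.0}
                for rng in arm[tk]["psg_kg_m2_s2"].values():
                    assert rng == {"min": 0.0, "max": 0.0}
                for frac in arm[tk]["recirculation_fraction"].values():
                    assert frac == 0.0
        assert rep.comparisons["wss_max_ratio_gpl_over_newtonian_plaque"] \
            == "unavailable"

    def test_report_roundtrips_losslessly(self, zero_flow_arms):
        arms, plaques = zero_flow_arms
        rep = summarize(arms, plaques, times=(0.4, 0.7), require_all=False)
        text = rep.to_json()
        again = SummaryReport.from_json(text)
        assert again.to_json() == text
        assert again.to_dict() == rep.to_dict()
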