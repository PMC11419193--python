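"""Bolus advection-reaction transport: closed forms, conservation, limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emboflow.config import BolusParams, FlowParams
from emboflow.errors import StagnationError
from emboflow.hemodynamics import solve_pressures
from emboflow.transport import (
    InjectionSpec,
    node_volumes,
    simulate,
    tag_embolization,
)
from emboflow.units import M3_TO_UL

from conftest import path_graph


class TestNodeVolumes:
    def test_single_edge_splits_cylinder_between_endpoints(self):
        vg = path_graph(2, dx_mm=10.0, radius_mm=1.0)
        dv = node_volumes(vg)
        expect = np.pi * (1e-3) ** 2 * 1e-2 / 2
        assert dv[0] == pytest.approx(expect, rel=1e-12)
        assert dv[0] == pytest.approx(1.5708e-8, rel=1e-4)

    def test_middle_node_of_a_path_gets_two_halves(self):
        vg = path_graph(3, dx_mm=5.0, radius_mm=0.8)
        dv = node_volumes(vg)
        assert dv[1] == pytest.approx(2 * dv[0], rel=1e-12)

    def test_total_volume_equals_sum_of_edge_cylinders(self):
        vg = path_graph(10, dx_mm=2.0, radius_mm=1.2)
        total_edges = sum(
            np.pi * (d["radius_mm"] * 1e-3) ** 2 * d["length_mm"] * 1e-3
            for _, _, d in vg.g.edges(data=True)
        )
        assert sum(node_volumes(vg).values()) == pytest.approx(total_edges, rel=1e-12)


class TestPipeBenchmark:
    def test_steady_profile_matches_exponential_decay(self, pipe_flow):
        """With a sustained unit inlet the discrete steady saturation along a
        uniform pipe converges to exp(-lambda x / u)."""
        vg, flow = pipe_flow
        bp = BolusParams(gamma_t=13.0)
        lam = bp.decay_rate
        assert lam == pytest.approx(13.0 * 0.1919 * 1532 / 1280, rel=1e-12)
        u = abs(next(iter(flow.velocities.values())))
        # injection long enough for the profile to reach steady state
        q = flow.q_total
        t_inj = 5.0 * (0.06 / u + 1.0 / lam)
        v_ul = q * t_inj * M3_TO_UL
        res = simulate(vg, flow, BolusParams(gamma_t=13.0, v_dcacl_ul=v_ul),
                       InjectionSpec(volume_ul=v_ul),
                       track_temperature=False, tail_closure=True)
        x = np.arange(vg.n_nodes) * 0.2e-3  # m
        ref = np.exp(-lam * x / u)
        sim = np.array([res.so_max[n] for n in vg.nodes])
        assert np.max(np.abs(sim / ref - 1.0)) < 0.01
        assert res.mass_closure_error() <= 1e-6

    def test_halving_dt_changes_total_damage_below_one_percent(self, pipe_flow):
        vg, flow = pipe_flow
        bp = BolusParams(gamma_t=13.0, v_dcacl_ul=200.0)
        inj = InjectionSpec(volume_ul=200.0)
        base = simulate(vg, flow, bp, inj, track_temperature=False, tail_closure=True)
        fine = simulate(vg, flow, bp, inj, dt=base.dt / 2,
                        track_temperature=False, tail_closure=True)
        assert abs(fine.damage_total - base.damage_total) / base.damage_total < 0.01
        for r in (base, fine):
            assert r.mass_closure_error() <= 1e-6


class TestLimits:
    def test_no_reaction_means_full_unreacted_escape(self, pipe_flow):
        vg, flow = pipe_flow
        bp = BolusParams(gamma_t=0.0, v_dcacl_ul=100.0)
        res = simulate(vg, flow, bp, InjectionSpec(100.0),
                       track_temperature=False, tail_closure=True)
        assert res.beta == pytest.approx(1.0, abs=1e-9)
        assert res.damage_total == pytest.approx(0.0, abs=1e-12)

    def test_instant_reaction_concentrates_damage_at_the_inlet(self, subject_flow, default_subject):
        vg = default_subject.graph
        bp = BolusParams(gamma_t=1e4, v_dcacl_ul=default_subject.injected_ul)
        res = simulate(vg, subject_flow, bp, track_temperature=False, tail_closure=True)
        assert res.beta < 1e-3
        # nearly everything reacts within a short distance of the root
        root_xyz = vg.position(vg.root)
        near = sum(
            d for n, d in res.damage.items()
            if np.linalg.norm(vg.position(n) - root_xyz) < 10.0
        )
        assert near > 0.95

    def test_stagnant_flow_is_an_error(self):
        vg = path_graph(4)
        sol = solve_pressures(vg, FlowParams(gamma_a=0.0))
        bp = BolusParams(v_dcacl_ul=100.0)
        with pytest.raises(StagnationError):
            simulate(vg, sol, bp, InjectionSpec(100.0))


class TestConservationAndBounds:
    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(
        gamma_t=st.floats(min_value=0.0, max_value=40.0),
        volume=st.floats(min_value=20.0, max_value=500.0),
    )
    def test_mass_closure_and_saturation_bounds(self, gamma_t, volume):
        vg = path_graph(40, dx_mm=1.0, radius_mm=1.0)
        flow = solve_pressures(vg, FlowParams(gamma_a=1e-13))
        bp = BolusParams(gamma_t=gamma_t, v_dcacl_ul=volume)
        res = simulate(vg, flow, bp, InjectionSpec(volume),
                       track_temperature=False, tail_closure=True)
        assert res.mass_closure_error() <= 1e-6
        for s in res.so_max.values():
            assert -1e-12 <= s <= 1.0 + 1e-9

    def test_stepping_and_closed_form_tail_agree(self, default_subject, subject_flow):
        vg = default_subject.graph
        bp = BolusParams(gamma_t=14.0, v_dcacl_ul=default_subject.injected_ul)
        stepped = simulate(vg, subject_flow, bp, track_temperature=False,
                           tail_closure=False)
        closed = simulate(vg, subject_flow, bp, track_temperature=False,
                          tail_closure=True)
        assert abs(stepped.beta - closed.beta) <= 5e-6
        diffs = [abs(stepped.damage[n] - closed.damage[n]) for n in vg.nodes]
        assert max(diffs) <= 2e-6
        assert closed.residual_fraction == pytest.approx(0.0, abs=1e-15)

    def test_damage_reach_shrinks_as_hydrolysis_accelerates(self, default_subject, subject_flow):
        """Fast hydrolysis confines the reaction near the injection site;
        slower hydrolysis lets the bolus act farther downstream."""
        import networkx as nx

        vg = default_subject.graph
        dist = nx.single_source_dijkstra_path_length(vg.g, vg.root, weight="length_mm")
        reaches = []
        for gt in (30.0, 60.0, 120.0, 240.0, 480.0):
            bp = BolusParams(gamma_t=gt, v_dcacl_ul=default_subject.injected_ul)
            res = simulate(vg, subject_flow, bp, track_temperature=False,
                           tail_closure=True)
            tagged = [n for n, d in res.damage.items() if d >= 0.005]
            assert tagged, f"no tagged node at gamma_t={gt}"
            reaches.append(max(dist[n] for n in tagged))
        assert all(a >= b - 1e-9 for a, b in zip(reaches, reaches[1:]))


class TestTemperature:
    def test_slug_injection_bounded_by_model_intrinsic_limit(self, default_subject, subject_flow):
        """A parcel of pure bolus reacting fully heats by at most
        h * rho_o / (W * rho_b * cp_b), ~319 K, in this energy model."""
        bp = BolusParams(gamma_t=14.0, v_dcacl_ul=default_subject.injected_ul)
        res = simulate(default_subject.graph, subject_flow, bp)
        bound = bp.h * bp.rho_o / (bp.molar_mass * bp.rho_b * bp.cp_b)
        assert 0.0 < res.t_max_rise < bound

    def test_hand_injection_raises_temperature_below_one_kelvin(
        self, default_subject, subject_flow
    ):
        """Delivered over a clinically realistic minute, the inlet is dilute
        and the predicted exothermic rise stays sub-degree."""
        bp = BolusParams(gamma_t=14.0, v_dcacl_ul=default_subject.injected_ul)
        res = simulate(default_subject.graph, subject_flow, bp,
                       InjectionSpec(default_subject.injected_ul, duration_s=60.0))
        assert 0.0 < res.t_max_rise < 1.0


class TestTagging:
    def test_threshold_splits_nodes(self):
        res = _fake_result({10: 0.02, 11: 0.005})
        pred = tag_embolization(res, 0.01)
        assert pred.tagged == {10: True, 11: False}

    def test_tiny_threshold_tags_everything_positive(self):
        res = _fake_result({1: 0.3, 2: 1e-9, 3: 0.0})
        pred = tag_embolization(res, 1e-12)
        assert pred.tagged == {1: True, 2: True, 3: False}

    def test_threshold_above_max_tags_nothing(self):
        res = _fake_result({1: 0.3, 2: 0.1})
        assert tag_embolization(res, 0.5).n_tagged == 0

    def test_threshold_domain_checked(self):
        with pytest.raises(ValueError):
            tag_embolization(_fake_result({1: 0.1}), 1.5)


def _fake_result(damage):
    from emboflow.transport import TransportResult

    return TransportResult(
        damage=damage, beta=0.0, t_max_rise=0.0, n_steps=0, t_end=0.0,
        residual_fraction=0.0, so_final={}, temp_rise_max={}, injected_ul=0.0,
        dt=1.0,
    )
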