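"""Vessel-graph physics: Poiseuille drops, junction losses, elasticity,
datum selection and the standalone tree residuals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vasoperf import (FlowParameters, ModelVariant, NetworkState, VascularNetwork,
                      elastic_radius, junction_drop, network_residuals,
                      poiseuille_drop, poiseuille_resistance, select_datum,
                      total_segment_drop, fixture_single_tube, fixture_y_bifurcation)
from vasoperf.network import (NetworkError, NodeRecord, SegmentRecord, junction_drops,
                              ROLE_INTERNAL, ROLE_ROOT, ROLE_TERMINAL)


class TestPoiseuille:
    def test_zero_flow_gives_zero_drop(self):
        assert poiseuille_drop(0.0, 3.0, 0.2, 3e-6) == 0.0

    def test_hand_evaluated_value(self):
        # 8 * 3e-6 * 1 * 1 / (pi * 0.1^4)
        assert poiseuille_drop(1.0, 1.0, 0.1, 3e-6) == pytest.approx(7.639437e-2, rel=1e-6)

    def test_linearity_in_flow(self):
        one = poiseuille_drop(1.3, 2.0, 0.15, 3e-6)
        assert poiseuille_drop(2.6, 2.0, 0.15, 3e-6) == pytest.approx(2 * one, rel=1e-14)

    @pytest.mark.parametrize("L,r", [(0.0, 0.1), (-1.0, 0.1), (1.0, 0.0), (1.0, -0.2)])
    def test_invalid_geometry_rejected(self, L, r):
        with pytest.raises(NetworkError):
            poiseuille_drop(1.0, L, r, 3e-6)


class TestJunctionDrop:
    RHO = 1.05e-6

    def test_straight_passthrough_loses_nothing(self):
        assert junction_drop(1.0, 0.1, 1.0, 0.1, 0.0, self.RHO) == pytest.approx(0.0, abs=1e-18)

    def test_stagnant_branch_hand_value(self):
        # bracket reduces to 1: rho q^2 / (2 pi^2 r^4)
        got = junction_drop(0.0, 0.08, 1.0, 0.1, 0.5, self.RHO)
        assert got == pytest.approx(5.31936e-4, rel=1e-5)

    def test_zero_datum_flow_rejected(self):
        with pytest.raises(NetworkError):
            junction_drop(1.0, 0.1, 0.0, 0.1, 0.3, self.RHO)

    @given(q_n=st.floats(0.0, 10.0), q_dat=st.floats(1e-6, 10.0),
           r_n=st.floats(0.01, 1.0), r_dat=st.floats(0.01, 1.0),
           theta=st.floats(0.0, np.pi))
    def test_nonnegative_for_codirectional_flow(self, q_n, q_dat, r_n, r_dat, theta):
        assert junction_drop(q_n, r_n, q_dat, r_dat, theta, self.RHO) >= -1e-18


class TestSelectDatum:
    def test_unique_inflow_is_datum(self):
        assert select_datum(["p", "c1", "c2"], {"p": 1.0, "c1": -0.6, "c2": -0.4}) == "p"

    def test_largest_inflow_wins(self):
        assert select_datum(["a", "b", "c"], {"a": 0.7, "b": 0.3, "c": -1.0}) == "a"

    def test_tie_breaks_to_lowest_id(self):
        assert select_datum(["b", "a", "c"], {"b": 0.5, "a": 0.5, "c": -1.0}) == "a"

    def test_no_inflow_returns_none(self):
        assert select_datum(["a", "b"], {"a": 0.0, "b": 0.0}) is None


class TestElasticRadius:
    def test_zero_transmural_pressure_keeps_rest_radius(self):
        assert elastic_radius(0.1, 0.22, 1000.0, 0.5, 2.0, 2.0) == pytest.approx(0.1)

    def test_hand_evaluated_dilation(self):
        # (1 - 0.25) * 0.01 / (0.022 * 1000) = 3.40909e-4
        got = elastic_radius(0.1, 0.22, 1000.0, 0.5, 3.0, 2.0)
        assert got - 0.1 == pytest.approx(3.40909e-4, rel=1e-5)

    def test_large_collapse_hits_clamp_floor(self):
        assert elastic_radius(0.1, 0.22, 1000.0, 0.5, 0.0, 1e4) == pytest.approx(0.05)

    @pytest.mark.parametrize("dp,expect_bigger", [(0.5, True), (-0.5, False)])
    def test_response_direction(self, dp, expect_bigger):
        r = elastic_radius(0.1, 0.22, 1000.0, 0.5, 2.0 + dp, 2.0)
        assert (r > 0.1) == expect_bigger


class TestTotalSegmentDrop:
    def _y_state(self, net, q_parent=1.0):
        q = np.zeros(3)
        q[net.segment_index("parent")] = q_parent
        q[net.segment_index("child1")] = 0.6 * q_parent
        q[net.segment_index("child2")] = 0.4 * q_parent
        return NetworkState(np.zeros(4), q, net.radii_init.copy())

    def test_linear_variant_is_pure_poiseuille(self, flow_params):
        net = fixture_y_bifurcation()
        state = self._y_state(net)
        k = net.segment_index("child1")
        got = total_segment_drop(net, "child1", state, flow_params,
                                 ModelVariant.from_name("linear"))
        want = poiseuille_drop(state.segment_flow[k], net.lengths[k],
                               net.radii_init[k], flow_params.viscosity)
        assert got == pytest.approx(want, rel=1e-14)

    def test_datum_segment_gets_no_junction_term(self, flow_params):
        net = fixture_y_bifurcation()
        state = self._y_state(net)
        k = net.segment_index("parent")
        got = total_segment_drop(net, "parent", state, flow_params,
                                 ModelVariant.from_name("junction"))
        want = poiseuille_drop(state.segment_flow[k], net.lengths[k],
                               net.radii_init[k], flow_params.viscosity)
        assert got == pytest.approx(want, rel=1e-14)

    def test_child_drop_is_poiseuille_plus_junction_loss(self, flow_params):
        net = fixture_y_bifurcation()
        state = self._y_state(net)
        k = net.segment_index("child1")
        kp = net.segment_index("parent")
        theta = np.arctan2(0.6, 1.0)  # printed geometry of the fixture
        want = (poiseuille_drop(0.6, net.lengths[k], net.radii_init[k], flow_params.viscosity)
                + junction_drop(0.6, net.radii_init[k], 1.0, net.radii_init[kp],
                                theta, flow_params.density))
        got = total_segment_drop(net, "child1", state, flow_params,
                                 ModelVariant.from_name("junction"))
        assert got == pytest.approx(want, rel=1e-12)


def _series_tube():
    nodes = [NodeRecord("in", 0, 0, ROLE_ROOT),
             NodeRecord("mid", 1, 0, ROLE_INTERNAL),
             NodeRecord("out", 3, 0, ROLE_TERMINAL)]
    segs = [SegmentRecord("s1", "in", "mid", 0.1, 1.0),
            SegmentRecord("s2", "mid", "out", 0.08, 2.0)]
    return VascularNetwork(nodes, segs)


class TestNetworkResiduals:
    def test_series_tube_analytic_solution_has_zero_residuals(self, flow_params):
        net = _series_tube()
        mu = flow_params.viscosity
        R1 = poiseuille_resistance(1.0, 0.1, mu)
        R2 = poiseuille_resistance(2.0, 0.08, mu)
        p_in, p_out = 4.0, 1.0
        q = (p_in - p_out) / (R1 + R2)
        p = np.array([p_in, p_in - R1 * q, p_out])
        state = NetworkState(p, np.array([q, q]), net.radii_init.copy())
        res = network_residuals(net, state, flow_params, {"in": p_in},
                                ModelVariant.from_name("linear"),
                                terminal_pressure={"out": p_out})
        assert np.max(np.abs(res)) < 1e-14 * max(p_in, q)

    def test_pressure_perturbation_is_local(self, flow_params):
        net = _series_tube()
        state = NetworkState(np.array([4.0, 2.5, 1.0]), np.array([0.3, 0.3]),
                             net.radii_init.copy())
        base = network_residuals(net, state, flow_params, {"in": 4.0},
                                 ModelVariant.from_name("linear"))
        state.node_pressure[net.node_index("mid")] += 0.1
        pert = network_residuals(net, state, flow_params, {"in": 4.0},
                                 ModelVariant.from_name("linear"))
        changed = np.flatnonzero(np.abs(pert - base) > 1e-15)
        # exactly the two incident segment rows change
        assert set(changed) == {net.segment_index("s1"), net.segment_index("s2")}

    def test_dimension_mismatch_rejected(self, flow_params):
        net = _series_tube()
        state = NetworkState(np.zeros(2), np.zeros(2), net.radii_init.copy())
        with pytest.raises(NetworkError):
            network_residuals(net, state, flow_params, {"in": 1.0},
                              ModelVariant.from_name("linear"))


class TestJunctionDropsAtNodes:
    def test_no_flow_skips_junction_terms(self, flow_params):
        net = fixture_y_bifurcation()
        state = NetworkState(np.zeros(4), np.zeros(3), net.radii_init.copy())
        assert np.all(junction_drops(net, state, flow_params) == 0.0)


class TestNetworkValidation:
    def test_root_with_high_degree_rejected(self):
        nodes = [NodeRecord("r", 0, 0, ROLE_ROOT), NodeRecord("a", 1, 0, ROLE_TERMINAL),
                 NodeRecord("b", 0, 1, ROLE_TERMINAL)]
        segs = [SegmentRecord("s1", "r", "a", 0.1, 1.0),
                SegmentRecord("s2", "r", "b", 0.1, 1.0)]
        with pytest.raises(NetworkError):
            VascularNetwork(nodes, segs)

    def test_component_without_terminal_rejected(self):
        nodes = [NodeRecord("r", 0, 0, ROLE_ROOT), NodeRecord("x", 1, 0, ROLE_ROOT)]
        segs = [SegmentRecord("s", "r", "x", 0.1, 1.0)]
        with pytest.raises(NetworkError):
            VascularNetwork(nodes, segs)

    def test_nonpositive_segment_geometry_rejected(self):
        with pytest.raises(NetworkError):
            SegmentRecord("s", "a", "b", radius=-0.1, length=1.0)
        with pytest.raises(NetworkError):
            SegmentRecord("s", "a", "b", radius=0.1, length=0.0)


class TestNetworkIO:
    def test_csv_roundtrip(self, tmp_path):
        net = fixture_y_bifurcation()
        net.to_csv(tmp_path / "nodes.csv", tmp_path / "segments.csv")
        back = VascularNetwork.from_csv(tmp_path / "nodes.csv", tmp_path / "segments.csv")
        assert back.node_ids == net.node_ids
        assert np.allclose(back.radii_init, net.radii_init)
        assert np.allclose(back.lengths, net.lengths)

    def test_graphml_roundtrip(self, tmp_path):
        net = fixture_single_tube()
        net.to_graphml(tmp_path / "net.graphml")
        back = VascularNetwork.from_graphml(tmp_path / "net.graphml")
        assert set(back.node_ids) == set(net.node_ids)
        assert np.allclose(sorted(back.radii_init), sorted(net.radii_init))
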