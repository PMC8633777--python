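"""Coupled assembly, Schur reduction and the nonlinear solves."""

import numpy as np
import pytest

from vasoperf import (BoundaryConditions, CapillaryParameters, CoupledProblem,
                      FlowParameters, ModelVariant, SolverSettings, kappa,
                      mmhg_to_kpa, poiseuille_resistance, solve, solve_linear)
from vasoperf.network import NetworkState, junction_drops


def loop_problem(minimal_loop, flow, cap, bc, variant="linear"):
    art, ven, grid = minimal_loop
    return CoupledProblem(art, ven, grid, flow, cap, bc,
                          variant=ModelVariant.from_name(variant))


def series_resistance(minimal_loop, flow, cap):
    art, ven, grid = minimal_loop
    mu = flow.viscosity
    eps = 3 * grid.dx
    R1 = poiseuille_resistance(art.lengths[0], art.radii_init[0], mu)
    R2 = poiseuille_resistance(ven.lengths[0], ven.radii_init[0], mu)
    ka = kappa(mu, eps, art.radii_init[0], 1)
    kv = kappa(mu, eps, ven.radii_init[0], 1)
    return float(R1 + ka + 1.0 / (cap.alpha * grid.cell_volume) + kv + R2)


class TestLinearSolve:
    def test_minimal_loop_matches_series_circuit(self, minimal_loop, flow_params,
                                                 capillary_params, bc):
        pr = loop_problem(minimal_loop, flow_params, capillary_params, bc)
        sol = solve_linear(pr)
        want = (bc.p_artery - bc.p_vein) / series_resistance(minimal_loop, flow_params,
                                                             capillary_params)
        got = sol.state.terminal_flows("artery")[0]
        assert got == pytest.approx(want, rel=1e-12)

    def test_equal_boundary_pressures_give_equilibrium(self, minimal_loop, flow_params,
                                                       capillary_params):
        bc = BoundaryConditions(2.0, 2.0)
        pr = loop_problem(minimal_loop, flow_params, capillary_params, bc)
        sol = solve_linear(pr)
        flows = np.concatenate([sol.state.x_N[pr.flow_cols[t]] for t in ("artery", "vein")])
        assert np.max(np.abs(flows)) < 1e-14
        assert np.allclose(sol.state.x_D, 2.0, atol=1e-12)

    def test_flows_scale_linearly_with_driving_pressure(self, minimal_loop, flow_params,
                                                        capillary_params):
        s1 = solve_linear(loop_problem(minimal_loop, flow_params, capillary_params,
                                       BoundaryConditions(2.0, 0.0)))
        s2 = solve_linear(loop_problem(minimal_loop, flow_params, capillary_params,
                                       BoundaryConditions(4.0, 0.0)))
        q1 = s1.state.terminal_flows("artery")[0]
        q2 = s2.state.terminal_flows("artery")[0]
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_linear_max_principle(self, solved_mini_organ, bc):
        sol = solved_mini_organ("linear")
        lo, hi = bc.p_vein - 1e-12, bc.p_artery + 1e-12
        assert np.all((sol.state.x_D >= lo) & (sol.state.x_D <= hi))
        assert np.all((sol.state.x_T >= lo) & (sol.state.x_T <= hi))


class TestSchurReduction:
    def test_schur_and_full_solves_agree(self, mini_organ, flow_params, capillary_params, bc):
        art, ven, grid = mini_organ
        pr = CoupledProblem(art, ven, grid, flow_params, capillary_params, bc,
                            variant=ModelVariant.from_name("linear"))
        a = solve_linear(pr, method="full")
        b = solve_linear(pr, method="schur")
        for ga, gb in ((a.state.x_N, b.state.x_N), (a.state.x_T, b.state.x_T),
                       (a.state.x_D, b.state.x_D)):
            scale = np.max(np.abs(ga))
            assert np.max(np.abs(ga - gb)) < 1e-9 * scale

    def test_single_cell_reduction_by_hand(self, minimal_loop, flow_params,
                                           capillary_params, bc):
        # one cell per compartment: the Schur complement is 2x2 scalar algebra
        pr = loop_problem(minimal_loop, flow_params, capillary_params, bc)
        aV = capillary_params.alpha * pr.grid.cell_volume
        ka = pr.couplings["artery"][0].kappa
        kv = pr.couplings["vein"][0].kappa
        A_DD = np.array([[aV + 1 / ka, -aV], [-aV, aV + 1 / kv]])
        A_DT = np.array([[-1 / ka, 0.0], [0.0, -1 / kv]])
        A_TD = np.array([[-1.0, 0.0], [0.0, -1.0]])
        schur_hand = np.eye(2) - A_TD @ np.linalg.solve(A_DD, A_DT)
        assert np.allclose(pr.schur, schur_hand, rtol=1e-12)

    def test_reduced_dimensions(self, mini_organ, flow_params, capillary_params, bc):
        art, ven, grid = mini_organ
        pr = CoupledProblem(art, ven, grid, flow_params, capillary_params, bc)
        n_nodes = sum(len(n.node_ids) - len(n.terminal_ids) for n in (art, ven))
        n_segs = sum(len(n.segment_ids) for n in (art, ven))
        n_term = sum(len(n.terminal_ids) for n in (art, ven))
        assert pr.n_N == n_nodes + n_segs
        assert pr.n_T == n_term
        assert pr.reduced_matrix().shape == (pr.n_N + pr.n_T,) * 2
        assert pr.n_D == 2 * grid.n_cells

    def test_darcy_block_symmetric(self, mini_organ, flow_params, capillary_params, bc):
        art, ven, grid = mini_organ
        pr = CoupledProblem(art, ven, grid, flow_params, capillary_params, bc)
        diff = pr.A_DD - pr.A_DD.T
        assert abs(diff).max() < 1e-14


class TestNonlinearSolve:
    def test_linear_variant_is_a_fixed_point(self, minimal_loop, flow_params,
                                             capillary_params, bc):
        pr = loop_problem(minimal_loop, flow_params, capillary_params, bc)
        lin = solve_linear(pr)
        non = solve(pr)
        assert np.max(np.abs(non.state.x_N - lin.state.x_N)) < 1e-12

    def test_junction_variant_without_junctions_matches_linear(self, minimal_loop,
                                                               flow_params,
                                                               capillary_params, bc):
        # the minimal loop has no degree-3 node, so the junction model is linear
        lin = solve(loop_problem(minimal_loop, flow_params, capillary_params, bc, "linear"))
        jun = solve(loop_problem(minimal_loop, flow_params, capillary_params, bc, "junction"))
        assert np.max(np.abs(jun.state.x_N - lin.state.x_N)) < 1e-12

    @pytest.mark.parametrize("variant", ["baseline", "elasticity", "junction"])
    def test_nonlinear_variants_converge_tightly(self, solved_mini_organ, variant):
        sol = solved_mini_organ(variant)
        pr = sol.state.problem
        assert sol.converged
        assert sol.residual_norm <= 1e-9 * pr.rhs_scale()
        # the unreduced residual agrees with the reduced one
        full = pr.full_residual(sol.state)
        assert np.linalg.norm(full) <= 1e-9 * pr.rhs_scale()

    def test_elastic_radii_respond_in_physical_direction(self, solved_mini_organ):
        sol = solved_mini_organ("baseline")
        pr = sol.state.problem
        for tree, cmp in (("artery", np.greater), ("vein", np.less)):
            net = pr.networks[tree]
            st = sol.state.network_state(tree)
            k = net.segment_index(net.root_segments()[net.root_ids[0]])
            # high-pressure arterial trunk dilates; low-pressure venous trunk narrows
            assert cmp(st.effective_radius[k], net.radii_init[k])

    def test_junction_losses_nonnegative_at_convergence(self, solved_mini_organ,
                                                        flow_params):
        sol = solved_mini_organ("baseline")
        pr = sol.state.problem
        for tree in ("artery", "vein"):
            st = sol.state.network_state(tree)
            assert np.all(junction_drops(pr.networks[tree], st, flow_params) >= 0.0)

    def test_root_flow_balance_every_variant(self, solved_mini_organ):
        for name in ("linear", "elasticity", "junction", "baseline"):
            sol = solved_mini_organ(name)
            pr = sol.state.problem
            Q = sol.state.terminal_flows("artery").sum()
            assert pr.root_flow_balance(sol.state) <= 1e-10 * abs(Q)
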