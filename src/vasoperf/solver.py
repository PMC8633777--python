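"""Coupled assembly and solution.

The full model is a quasi-linear block system A(x) x = b with unknowns

    x_N : nodal pressures (non-terminal) and segment flows, both trees
    x_T : terminal pressures, both trees
    x_D : Darcy cell pressures, both compartments

Rows: per segment a pressure-drop equation, per internal node mass
conservation, per root a Dirichlet pressure equation (the global
root-flow balance is then implied and checked post-solve), per terminal
the pressure-continuity equation through kappa, and per Darcy cell the
TPFA balance with perfusion exchange and mollified terminal sources.
In the Darcy rows the terminal flow Q_t is eliminated through the
continuity equation, adding (1/kappa) w w^T to the Darcy operator and
-w/kappa couplings to the terminal pressures; this removes the
constant-pressure nullspace, so the Darcy block is invertible and
state-independent.

That invertibility is what the Schur reduction exploits: the Darcy
correction C = A_DD^{-1} A_DT is computed once with a sparse LU
factorization (never forming the inverse), giving x_D = -C x_T exactly
and a reduced system over (x_N, x_T) only.  The nonlinear variants are
solved on this reduced residual with a Powell-dogleg trust-region
iteration (MINPACK hybrid), initialized from the linear model's direct
solution; if the trust-region iteration stalls, a damped Picard
iteration on the frozen-coefficient linear system takes over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import root

from .coupling import TerminalCoupling, build_couplings
from .darcy import CapillaryParameters, DarcyField, assemble_tpfa, perfusion_exchange
from .grid import StructuredGrid
from .network import (FlowParameters, ModelVariant, NetworkState, VascularNetwork,
                      elastic_radius, junction_drops, poiseuille_resistance)

log = logging.getLogger(__name__)

TREES = ("artery", "vein")


class AssemblyError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Carries the best iterate and its residual norm."""

    def __init__(self, message, best_state=None, residual_norm=None):
        super().__init__(message)
        self.best_state = best_state
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet pressures (kPa) applied at every root of each tree."""

    p_artery: float
    p_vein: float

    def root_pressure(self, tree: str) -> float:
        return self.p_artery if tree == "artery" else self.p_vein


@dataclass
class SolverSettings:
    tolerance: float = 1e-9      # relative residual: ||F|| <= tol * (1 + ||b||)
    max_iterations: int = 200
    picard_damping: float = 0.7
    seed: int | None = None      # unused unless stochastic perturbation is enabled


@dataclass
class CoupledState:
    """Solution container with per-tree views."""

    x_N: np.ndarray
    x_T: np.ndarray
    x_D: np.ndarray
    problem: "CoupledProblem"

    def network_state(self, tree: str) -> NetworkState:
        pr = self.problem
        net = pr.networks[tree]
        p = np.empty(len(net.node_ids))
        for i, nid in enumerate(net.node_ids):
            col = pr.node_col[tree].get(nid)
            p[i] = self.x_N[col] if col is not None else self.x_T[pr.term_col[tree][nid]]
        q = self.x_N[pr.flow_cols[tree]]
        r_eff = pr.effective_radii(tree, self) if pr.variant.elasticity_enabled \
            else net.radii_init.copy()
        return NetworkState(p, q, r_eff)

    def terminal_pressures(self, tree: str) -> np.ndarray:
        pr = self.problem
        return np.array([self.x_T[pr.term_col[tree][c.terminal_id]]
                         for c in pr.couplings[tree]])

    def terminal_flows(self, tree: str) -> np.ndarray:
        """Signed source strengths Q_t into the compartment."""
        pr = self.problem
        q = self.x_N[pr.flow_cols[tree]]
        return np.array([c.flow_sign * q[c.segment_index] for c in pr.couplings[tree]])

    @property
    def darcy(self) -> DarcyField:
        m = self.problem.grid.n_cells
        return DarcyField(self.x_D[:m], self.x_D[m:])


@dataclass
class CoupledSolution:
    state: CoupledState
    variant: ModelVariant
    residual_norm: float
    converged: bool
    iterations: int
    residual_history: list = field(default_factory=list)
    used_fallback: bool = False


class CoupledProblem:
    """Index bookkeeping plus assembled constant blocks for one geometry."""

    def __init__(self, network_artery: VascularNetwork, network_vein: VascularNetwork,
                 grid: StructuredGrid, flow: FlowParameters, capillary: CapillaryParameters,
                 bc: BoundaryConditions, variant: ModelVariant = ModelVariant(),
                 couplings: dict[str, list[TerminalCoupling]] | None = None,
                 epsilon: float | None = None):
        if network_artery.tree != "artery" or network_vein.tree != "vein":
            raise AssemblyError(
                "compartment mismatch: networks must be passed as (artery, vein), got "
                f"({network_artery.tree}, {network_vein.tree})")
        self.networks = {"artery": network_artery, "vein": network_vein}
        self.grid = grid
        self.flow = flow
        self.capillary = capillary
        self.bc = bc
        self.variant = variant
        if couplings is None:
            couplings = {t: build_couplings(self.networks[t], grid, flow.viscosity, epsilon)
                         for t in TREES}
        self.couplings = couplings
        for t in TREES:
            if not self.couplings[t]:
                raise AssemblyError(f"{t} tree has no terminal coupling")
        self._index()
        self._assemble_constant_blocks()
        self._factorize_darcy()

    # -- indexing -------------------------------------------------------------

    def _index(self):
        self.node_col: dict[str, dict[str, int]] = {t: {} for t in TREES}
        self.term_col: dict[str, dict[str, int]] = {t: {} for t in TREES}
        self.flow_cols: dict[str, np.ndarray] = {}
        nN = 0
        for t in TREES:
            net = self.networks[t]
            for nid in net.node_ids:
                if net.nodes[nid].role != "terminal":
                    self.node_col[t][nid] = nN
                    nN += 1
            self.flow_cols[t] = np.arange(nN, nN + len(net.segment_ids))
            nN += len(net.segment_ids)
        self.n_N = nN
        nT = 0
        for t in TREES:
            for c in self.couplings[t]:
                self.term_col[t][c.terminal_id] = nT
                nT += 1
        self.n_T = nT
        self.n_D = 2 * self.grid.n_cells
        self.n_total = self.n_N + self.n_T + self.n_D

        # per-segment endpoint pressure columns, split into x_N vs x_T space
        self._seg_pcols = {}
        for t in TREES:
            net = self.networks[t]
            cols = []
            for k, sid in enumerate(net.segment_ids):
                s = net.segments[sid]
                cols.append((self._pressure_col(t, s.node_a), self._pressure_col(t, s.node_b)))
            self._seg_pcols[t] = cols

        # midpoint Darcy cell per segment (for elastic P_ext sampling)
        self._seg_midcell = {}
        offset = {"artery": 0, "vein": self.grid.n_cells}
        for t in TREES:
            net = self.networks[t]
            mids = 0.5 * (net.positions[net.seg_a] + net.positions[net.seg_b])
            self._seg_midcell[t] = np.array(
                [offset[t] + self.grid.nearest_cell(m) for m in mids])

    def _pressure_col(self, tree: str, node_id: str) -> tuple[str, int]:
        if node_id in self.node_col[tree]:
            return ("N", self.node_col[tree][node_id])
        return ("T", self.term_col[tree][node_id])

    # -- constant blocks ------------------------------------------------------

    def _assemble_constant_blocks(self):
        grid, cap, mu = self.grid, self.capillary, self.flow.viscosity
        m = grid.n_cells
        # Darcy block: TPFA per compartment + exchange + terminal elimination
        La = assemble_tpfa(grid, cap.K_artery, mu)
        Lv = assemble_tpfa(grid, cap.K_vein, mu)
        aV = cap.alpha * grid.cell_volume
        E = sp.identity(m, format="csr") * aV
        A_DD = sp.bmat([[La + E, -E], [-E, Lv + E]], format="lil")
        A_DT = sp.lil_matrix((self.n_D, self.n_T))
        A_TD = sp.lil_matrix((self.n_T, self.n_D))
        offset = {"artery": 0, "vein": m}
        for t in TREES:
            off = offset[t]
            for c in self.couplings[t]:
                tc = self.term_col[t][c.terminal_id]
                cells = c.mollifier.cells + off
                w = c.mollifier.weights
                A_DD[np.ix_(cells, cells)] += np.outer(w, w) / c.kappa
                for cell, wi in zip(cells, w):
                    A_DT[cell, tc] = -wi / c.kappa
                    A_TD[tc, cell] = -wi
        self.A_DD = A_DD.tocsc()
        self.A_DT = A_DT.tocsr()
        self.A_TD = A_TD.tocsr()
        self.A_TT = sp.identity(self.n_T, format="csr")

        # Terminal rows' coupling to flows: -kappa * sign * q_seg
        A_TN = sp.lil_matrix((self.n_T, self.n_N))
        for t in TREES:
            for c in self.couplings[t]:
                tc = self.term_col[t][c.terminal_id]
                A_TN[tc, self.flow_cols[t][c.segment_index]] = -c.kappa * c.flow_sign
        self.A_TN = A_TN.tocsr()

        # Network rows (linear base, rest radii): A_NN x_N + A_NT x_T = b_N
        rows_N, cols_N, vals_N = [], [], []
        rows_T, cols_T, vals_T = [], [], []
        b_N = np.zeros(self.n_N)
        row = 0
        self._seg_rows = {}
        self._root_rows = {}
        for t in TREES:
            net = self.networks[t]
            R = poiseuille_resistance(net.lengths, net.radii_init, self.flow.viscosity)
            self._seg_rows[t] = np.arange(row, row + len(net.segment_ids))
            for k, sid in enumerate(net.segment_ids):
                (sa, ca), (sb, cb) = self._seg_pcols[t][k]
                for space, col, val in ((sa, ca, 1.0), (sb, cb, -1.0)):
                    (rows_N if space == "N" else rows_T).append(row)
                    (cols_N if space == "N" else cols_T).append(col)
                    (vals_N if space == "N" else vals_T).append(val)
                rows_N.append(row); cols_N.append(self.flow_cols[t][k]); vals_N.append(-R[k])
                row += 1
            for nid in net.internal_ids:
                i = net.node_index(nid)
                for k in np.flatnonzero(net.seg_b == i):
                    rows_N.append(row); cols_N.append(self.flow_cols[t][k]); vals_N.append(1.0)
                for k in np.flatnonzero(net.seg_a == i):
                    rows_N.append(row); cols_N.append(self.flow_cols[t][k]); vals_N.append(-1.0)
                row += 1
            self._root_rows[t] = np.arange(row, row + len(net.root_ids))
            for rid in net.root_ids:
                rows_N.append(row); cols_N.append(self.node_col[t][rid]); vals_N.append(1.0)
                b_N[row] = self.bc.root_pressure(t)
                row += 1
        assert row == self.n_N
        self.A_NN = sp.csr_matrix((vals_N, (rows_N, cols_N)), shape=(self.n_N, self.n_N))
        self.A_NT = sp.csr_matrix((vals_T, (rows_T, cols_T)), shape=(self.n_N, self.n_T))
        self.b_N = b_N
        self.base_resistance = {
            t: poiseuille_resistance(self.networks[t].lengths, self.networks[t].radii_init,
                                     self.flow.viscosity) for t in TREES}

    def _factorize_darcy(self):
        self._darcy_lu = spla.splu(self.A_DD)
        self.C = self._darcy_lu.solve(self.A_DT.toarray())   # A_DD^{-1} A_DT, n_D x n_T
        self.schur = (self.A_TT - self.A_TD @ self.C)        # dense T x T: B/A_DD
        self.schur = np.asarray(self.schur)

    # -- assembly views -------------------------------------------------------

    def full_matrix(self) -> sp.csr_matrix:
        """The linear-variant block matrix over (x_N, x_T, x_D)."""
        return sp.bmat([
            [self.A_NN, self.A_NT, None],
            [self.A_TN, self.A_TT, self.A_TD],
            [None, self.A_DT, self.A_DD],
        ], format="csr")

    def full_rhs(self) -> np.ndarray:
        return np.concatenate([self.b_N, np.zeros(self.n_T), np.zeros(self.n_D)])

    def reduced_matrix(self, A_NN=None, A_NT=None) -> sp.csr_matrix:
        """Schur-reduced linear operator over (x_N, x_T)."""
        return sp.bmat([
            [self.A_NN if A_NN is None else A_NN, self.A_NT if A_NT is None else A_NT],
            [self.A_TN, sp.csr_matrix(self.schur)],
        ], format="csr")

    def darcy_from_terminals(self, x_T: np.ndarray) -> np.ndarray:
        """Back-substitution: x_D = -A_DD^{-1} A_DT x_T."""
        return -self.C @ x_T

    # -- nonlinear residual on the reduced unknowns ---------------------------

    def effective_radii(self, tree: str, state: CoupledState) -> np.ndarray:
        net = self.networks[tree]
        p_a, p_b = self._endpoint_pressures(tree, state.x_N, state.x_T)
        p_in = 0.5 * (p_a + p_b)
        p_ext = state.x_D[self._seg_midcell[tree]]
        return elastic_radius(net.radii_init, net.wall_ratios,
                              self.flow.youngs_modulus(tree), self.flow.poisson, p_in, p_ext)

    def _endpoint_pressures(self, tree, x_N, x_T):
        cols = self._seg_pcols[tree]
        p_a = np.array([x_N[c] if s == "N" else x_T[c] for (s, c), _ in cols])
        p_b = np.array([x_N[c] if s == "N" else x_T[c] for _, (s, c) in cols])
        return p_a, p_b

    def nonlinear_correction(self, x_N, x_T, x_D) -> np.ndarray:
        """Residual correction n(x) added to the linear residual's segment
        rows: replaces rest-radius Poiseuille drops with effective-radius
        ones and adds signed junction losses."""
        corr = np.zeros(self.n_N)
        st = CoupledState(x_N, x_T, x_D, self)
        for t in TREES:
            net = self.networks[t]
            q = x_N[self.flow_cols[t]]
            r = net.radii_init
            extra = np.zeros(len(q))
            if self.variant.elasticity_enabled:
                r = self.effective_radii(t, st)
                R_eff = poiseuille_resistance(net.lengths, r, self.flow.viscosity)
                extra += (R_eff - self.base_resistance[t]) * q
            if self.variant.junction_enabled:
                ns = NetworkState(np.zeros(len(net.node_ids)), q, r)
                extra += np.sign(q) * junction_drops(net, ns, self.flow)
            # segment residual = p_a - p_b - drop; the linear part already
            # carries -R0 q, so the correction enters with a minus sign
            corr[self._seg_rows[t]] = -extra
        return corr

    def reduced_residual(self, y: np.ndarray) -> np.ndarray:
        x_N, x_T = y[:self.n_N], y[self.n_N:]
        lin_N = self.A_NN @ x_N + self.A_NT @ x_T - self.b_N
        lin_T = self.A_TN @ x_N + self.schur @ x_T
        res = np.concatenate([lin_N, lin_T])
        if not self.variant.is_linear:
            res[:self.n_N] += self.nonlinear_correction(x_N, x_T,
                                                        self.darcy_from_terminals(x_T))
        return res

    def full_residual(self, state: CoupledState) -> np.ndarray:
        """Residual of the unreduced system F(x) = A(x)x - b."""
        x_N, x_T, x_D = state.x_N, state.x_T, state.x_D
        res_N = self.A_NN @ x_N + self.A_NT @ x_T - self.b_N
        res_T = self.A_TN @ x_N + self.A_TT @ x_T + self.A_TD @ x_D
        res_D = self.A_DT @ x_T + self.A_DD @ x_D
        if not self.variant.is_linear:
            res_N = res_N + self.nonlinear_correction(x_N, x_T, x_D)
        return np.concatenate([res_N, res_T, res_D])

    # -- diagnostics ----------------------------------------------------------

    def rhs_scale(self) -> float:
        return 1.0 + float(np.linalg.norm(self.b_N))

    def root_flow_balance(self, state: CoupledState) -> float:
        """|sum of signed root flows| over both trees (implied Eq.:
        total arterial inflow equals total venous outflow)."""
        total = 0.0
        for t in TREES:
            net = self.networks[t]
            q = state.x_N[self.flow_cols[t]]
            for rid, sid in net.root_segments().items():
                k = net.segment_index(sid)
                # flow into the network from this root: +q if the root is
                # node_a of its segment, -q if it is node_b
                s = 1.0 if net.seg_a[k] == net.node_index(rid) else -1.0
                total += s * q[k]
        return abs(total)


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def solve_linear(problem: CoupledProblem, method: str = "schur") -> CoupledSolution:
    """Direct sparse solve of the linear variant (also the initializer for
    every nonlinear variant).  ``method`` 'full' solves the unreduced block
    matrix; 'schur' solves the reduced system and back-substitutes."""
    if method == "full":
        A = problem.full_matrix()
        b = problem.full_rhs()
        x = spla.spsolve(A.tocsc(), b)
        state = CoupledState(x[:problem.n_N],
                             x[problem.n_N:problem.n_N + problem.n_T],
                             x[problem.n_N + problem.n_T:], problem)
    elif method == "schur":
        A = problem.reduced_matrix()
        b = np.concatenate([problem.b_N, np.zeros(problem.n_T)])
        y = spla.spsolve(A.tocsc(), b)
        x_T = y[problem.n_N:]
        state = CoupledState(y[:problem.n_N], x_T,
                             problem.darcy_from_terminals(x_T), problem)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(state.x_N)):
        raise AssemblyError("linear solve produced non-finite values; "
                            "check connectivity and couplings")
    res = np.concatenate([
        problem.A_NN @ state.x_N + problem.A_NT @ state.x_T - problem.b_N,
        problem.A_TN @ state.x_N + problem.A_TT @ state.x_T + problem.A_TD @ state.x_D,
        problem.A_DT @ state.x_T + problem.A_DD @ state.x_D,
    ])
    rn = float(np.linalg.norm(res))
    lin_variant = ModelVariant(False, False)
    return CoupledSolution(state, lin_variant, rn, rn <= 1e-9 * problem.rhs_scale(), 1)


def _picard(problem: CoupledProblem, y0: np.ndarray, settings: SolverSettings):
    """Damped Picard on the quasi-linear form: freeze effective radii and
    junction losses at the current iterate, re-solve the reduced linear
    system, and damp."""
    y = y0.copy()
    scale = problem.rhs_scale()
    history = []
    best = (np.inf, y)
    for it in range(settings.max_iterations):
        x_N, x_T = y[:problem.n_N], y[problem.n_N:]
        x_D = problem.darcy_from_terminals(x_T)
        st = CoupledState(x_N, x_T, x_D, problem)
        # frozen-coefficient segment rows
        A_NN = problem.A_NN.tolil(copy=True)
        rhs_corr = np.zeros(problem.n_N)
        for t in TREES:
            net = problem.networks[t]
            q = x_N[problem.flow_cols[t]]
            r = net.radii_init
            if problem.variant.elasticity_enabled:
                r = problem.effective_radii(t, st)
                R_eff = poiseuille_resistance(net.lengths, r, problem.flow.viscosity)
                rows = problem._seg_rows[t]
                for k, rr in enumerate(rows):
                    A_NN[rr, problem.flow_cols[t][k]] = -R_eff[k]
            if problem.variant.junction_enabled:
                ns = NetworkState(np.zeros(len(net.node_ids)), q, r)
                rhs_corr[problem._seg_rows[t]] += np.sign(q) * junction_drops(net, ns, problem.flow)
        A = problem.reduced_matrix(A_NN=A_NN.tocsr())
        b = np.concatenate([problem.b_N + rhs_corr, np.zeros(problem.n_T)])
        y_new = spla.spsolve(A.tocsc(), b)
        y = (1 - settings.picard_damping) * y + settings.picard_damping * y_new
        rn = float(np.linalg.norm(problem.reduced_residual(y)))
        history.append(rn)
        if rn < best[0]:
            best = (rn, y.copy())
        if rn <= settings.tolerance * scale:
            return y, rn, it + 1, history
    return best[1], best[0], settings.max_iterations, history


def solve_nonlinear(problem: CoupledProblem, settings: SolverSettings | None = None
                    ) -> CoupledSolution:
    """Solve the (possibly nonlinear) coupled model on the Schur-reduced
    unknowns, starting from the linear model's solution."""
    settings = settings or SolverSettings()
    lin = solve_linear(problem, method="schur")
    y0 = np.concatenate([lin.state.x_N, lin.state.x_T])
    scale = problem.rhs_scale()
    if problem.variant.is_linear:
        return CoupledSolution(lin.state, problem.variant, lin.residual_norm,
                               lin.residual_norm <= settings.tolerance * scale, 1)

    history = []

    def fun(y):
        r = problem.reduced_residual(y)
        history.append(float(np.linalg.norm(r)))
        return r

    sol = root(fun, y0, method="hybr", options={"xtol": 1e-13,
                                                "maxfev": 400 * (len(y0) + 1)})
    y = sol.x
    rn = float(np.linalg.norm(problem.reduced_residual(y)))
    used_fallback = False
    iterations = int(sol.nfev)
    if rn > settings.tolerance * scale:
        log.warning("dogleg iteration stalled at ||F||=%.3e; falling back to damped Picard", rn)
        used_fallback = True
        y, rn, its, hist2 = _picard(problem, y, settings)
        history.extend(hist2)
        iterations += its
    x_T = y[problem.n_N:]
    state = CoupledState(y[:problem.n_N], x_T, problem.darcy_from_terminals(x_T), problem)
    converged = rn <= settings.tolerance * scale
    if not converged:
        raise ConvergenceError(
            f"nonlinear solve did not reach tolerance: ||F||={rn:.3e} "
            f"(target {settings.tolerance * scale:.3e})",
            best_state=state, residual_norm=rn)
    return CoupledSolution(state, problem.variant, rn, True, iterations,
                           history, used_fallback)


def solve(problem: CoupledProblem, settings: SolverSettings | None = None) -> CoupledSolution:
    """Entry point: direct solve for the linear variant, trust-region
    iteration otherwise."""
    return solve_nonlinear(problem, settings)
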