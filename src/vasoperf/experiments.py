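"""Experiment drivers: summary metrics, model-variant comparison,
occlusion sweeps and field export.

Hydraulic resistance is reported as R = (P_in - P_out)/Q in
kPa·s·mm⁻³ ≡ kg·mm⁻⁴·s⁻¹.  The total resistance is decomposed into
arterial network, arterial compartment, venous compartment and venous
network contributions through flow-weighted interface pressures:

    P_in  >  P̄_aT  >  P̄_X  >  P̄_vT  >  P_out

where P̄_aT / P̄_vT are the flow-weighted mean terminal pressures and
P̄_X is the exchange-flow-weighted mean of (P_a+P_v)/2 over the bed
(the perfusion drop is split evenly between the two compartment
resistances).  Because adjacent components share interface values, the
four drops telescope *exactly* to P_in - P_out; this additive
convention is ours, chosen so the decomposition closes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .darcy import perfusion_exchange
from .network import ModelVariant, VascularNetwork
from .solver import (BoundaryConditions, ConvergenceError, CoupledProblem,
                     CoupledSolution, SolverSettings, solve)
from .synthetic import OcclusionSpec, apply_occlusion
from .units import KPA_TO_MMHG

log = logging.getLogger(__name__)


@dataclass
class ExperimentMetrics:
    """Whole-system summary of one converged run (mm/s/kPa units)."""

    variant: str
    Q_total: float                     # mm^3/s, total arterial root inflow
    R_total: float                     # kPa s mm^-3 == kg mm^-4 s^-1
    R_arterial_network: float
    R_venous_network: float
    R_arterial_compartment: float
    R_venous_compartment: float
    drop_fractions: dict[str, float]   # % of P_in - P_out per component
    per_root_flow: dict[str, float]    # signed inflow per root node
    total_exchange: float              # mm^3/s through the perfusion term
    flow_reversal_count: int = 0       # venous segments with sign flips vs reference

    @property
    def component_resistances(self) -> dict[str, float]:
        return {"arterial_network": self.R_arterial_network,
                "arterial_compartment": self.R_arterial_compartment,
                "venous_compartment": self.R_venous_compartment,
                "venous_network": self.R_venous_network}

    def component_drops_kpa(self) -> dict[str, float]:
        return {k: v * self.Q_total for k, v in self.component_resistances.items()}

    def total_drop_mmHg(self) -> float:
        return sum(self.component_drops_kpa().values()) * KPA_TO_MMHG

    def as_row(self) -> dict:
        return {
            "variant": self.variant,
            "Q_total_mm3_s": self.Q_total,
            "R_total": self.R_total,
            "R_aN": self.R_arterial_network,
            "R_vN": self.R_venous_network,
            "R_aC": self.R_arterial_compartment,
            "R_vC": self.R_venous_compartment,
            "exchange_mm3_s": self.total_exchange,
            "flow_reversals": self.flow_reversal_count,
        }


def _root_inflows(problem: CoupledProblem, solution: CoupledSolution, tree: str) -> dict[str, float]:
    net = problem.networks[tree]
    q = solution.state.x_N[problem.flow_cols[tree]]
    out = {}
    for rid, sid in net.root_segments().items():
        k = net.segment_index(sid)
        s = 1.0 if net.seg_a[k] == net.node_index(rid) else -1.0
        out[rid] = s * q[k]
    return out


def compute_metrics(solution: CoupledSolution, reference: CoupledSolution | None = None
                    ) -> ExperimentMetrics:
    """Summary metrics of a converged coupled solution.

    ``reference`` (e.g. the unoccluded run on the same geometry) enables
    the venous flow-reversal count.
    """
    if not solution.converged:
        raise ConvergenceError(
            f"refusing metrics of a non-converged solution "
            f"(||F||={solution.residual_norm:.3e})")
    pr: CoupledProblem = solution.state.problem
    p_in, p_out = pr.bc.p_artery, pr.bc.p_vein

    art_in = _root_inflows(pr, solution, "artery")
    ven_in = _root_inflows(pr, solution, "vein")
    Q = sum(art_in.values())

    # flow-weighted interface pressures
    qa = solution.state.terminal_flows("artery")        # source strengths, sum ~= Q
    pa = solution.state.terminal_pressures("artery")
    qv = -solution.state.terminal_flows("vein")         # flow into the vein tree
    pv = solution.state.terminal_pressures("vein")
    p_aT = float(qa @ pa / qa.sum())
    p_vT = float(qv @ pv / qv.sum())

    d = solution.state.darcy
    F = perfusion_exchange(d.P_artery, d.P_vein, pr.capillary.alpha, pr.grid.cell_volume)
    Fsum = float(F.sum())
    p_X = float(F @ ((d.P_artery + d.P_vein) / 2.0) / Fsum)

    drops = {
        "arterial_network": p_in - p_aT,
        "arterial_compartment": p_aT - p_X,
        "venous_compartment": p_X - p_vT,
        "venous_network": p_vT - p_out,
    }
    total = p_in - p_out
    reversals = 0
    if reference is not None:
        q_now = solution.state.x_N[pr.flow_cols["vein"]]
        q_ref = reference.state.x_N[reference.state.problem.flow_cols["vein"]]
        reversals = int(np.count_nonzero(np.sign(q_now) * np.sign(q_ref) < 0))

    return ExperimentMetrics(
        variant=solution.variant.name,
        Q_total=Q,
        R_total=total / Q,
        R_arterial_network=drops["arterial_network"] / Q,
        R_venous_network=drops["venous_network"] / Q,
        R_arterial_compartment=drops["arterial_compartment"] / Q,
        R_venous_compartment=drops["venous_compartment"] / Q,
        drop_fractions={k: 100.0 * v / total for k, v in drops.items()},
        per_root_flow={**art_in, **{k: -v for k, v in ven_in.items()}},
        total_exchange=Fsum,
        flow_reversal_count=reversals,
    )


VARIANT_NAMES = ("baseline", "elasticity", "junction", "linear")


def run_variant_comparison(network_artery, network_vein, grid, flow, capillary, bc,
                           settings: SolverSettings | None = None,
                           variants=VARIANT_NAMES) -> pd.DataFrame:
    """One metrics row per named model variant on identical geometry."""
    rows = []
    for name in variants:
        problem = CoupledProblem(network_artery, network_vein, grid, flow, capillary, bc,
                                 variant=ModelVariant.from_name(name))
        try:
            sol = solve(problem, settings)
        except ConvergenceError as err:
            log.error("variant %s failed to converge: %s", name, err)
            rows.append({"variant": name, "error": str(err)})
            continue
        rows.append(compute_metrics(sol).as_row())
    return pd.DataFrame(rows)


def default_rates() -> np.ndarray:
    """Occlusion sweep grid: 5% .. 100% in 5% steps."""
    return np.round(np.arange(0.05, 1.0001, 0.05), 10)


def run_occlusion_sweep(network_artery, network_vein, grid, flow, capillary, bc,
                        targets: dict[str, tuple[str, str]] | list,
                        rates=None, variants=("baseline",),
                        settings: SolverSettings | None = None) -> pd.DataFrame:
    """R_total (and friends) as a function of occlusion rate per target.

    ``targets``: mapping label -> (tree, segment_id), or a list of
    (tree, segment_id) pairs.  Each (variant, target, rate) row is one
    full solve; non-convergent rows are flagged and the sweep continues.
    """
    if isinstance(targets, (list, tuple)):
        targets = {f"{t}:{sid}": (t, sid) for t, sid in targets}
    rates = default_rates() if rates is None else np.asarray(rates, float)
    nets0 = {"artery": network_artery, "vein": network_vein}
    rows = []
    for vname in variants:
        variant = ModelVariant.from_name(vname)
        ref = solve(CoupledProblem(network_artery, network_vein, grid, flow, capillary,
                                   bc, variant=variant), settings)
        ref_metrics = compute_metrics(ref)
        for label, (tree, sid) in targets.items():
            for rate in rates:
                nets = dict(nets0)
                nets[tree] = apply_occlusion(nets0[tree], OcclusionSpec(sid, float(rate)))
                problem = CoupledProblem(nets["artery"], nets["vein"], grid, flow,
                                         capillary, bc, variant=variant)
                row = {"variant": vname, "target": label, "tree": tree,
                       "segment": sid, "rate": float(rate)}
                try:
                    sol = solve(problem, settings)
                    met = compute_metrics(sol, reference=ref)
                    row.update(met.as_row())
                    row["variant"] = vname
                except ConvergenceError as err:
                    row["error"] = str(err)
                    log.error("occlusion %s rate %.2f (%s): %s", label, rate, vname, err)
                rows.append(row)
        rows.append({"variant": vname, "target": "none", "tree": "", "segment": "",
                     "rate": 0.0, **ref_metrics.as_row(), "variant": vname})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Field export
# ---------------------------------------------------------------------------

def _write_legacy_vtk(path, grid, fields: dict[str, np.ndarray]):
    """Minimal legacy ASCII VTK STRUCTURED_POINTS writer (cell-centred
    scalars written as point data on the cell-centre lattice)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvasoperf fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {grid.nx} {grid.ny} 1\n")
        fh.write(f"ORIGIN {0.5 * grid.dx} {0.5 * grid.dx} 0\n")
        fh.write(f"SPACING {grid.dx} {grid.dx} {grid.dx}\n")
        fh.write(f"POINT_DATA {grid.nx * grid.ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = np.nan_to_num(arr, nan=0.0).T.ravel()  # x fastest, per VTK
            fh.write("\n".join(f"{v:.17g}" for v in flat) + "\n")


def export_fields(solution: CoupledSolution, out_dir, prefix: str = "run"):
    """Write P_a, P_v and the perfusion map as CSV + legacy VTK, and both
    networks as GraphML with flow attributes.  Returns the written paths."""
    import os
    pr = solution.state.problem
    grid = pr.grid
    d = solution.state.darcy
    Pa = grid.scatter(d.P_artery)
    Pv = grid.scatter(d.P_vein)
    F = grid.scatter(perfusion_exchange(d.P_artery, d.P_vein, pr.capillary.alpha,
                                        grid.cell_volume))
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, arr in (("P_artery_kPa", Pa), ("P_vein_kPa", Pv), ("perfusion_mm3_s", F)):
        p = os.path.join(out_dir, f"{prefix}_{name}.csv")
        np.savetxt(p, arr.T, delimiter=",", fmt="%.17g")
        paths[name + "_csv"] = p
    vtk_path = os.path.join(out_dir, f"{prefix}_fields.vtk")
    _write_legacy_vtk(vtk_path, grid, {"P_artery_kPa": Pa, "P_vein_kPa": Pv,
                                       "perfusion_mm3_s": F})
    paths["vtk"] = vtk_path
    for tree in ("artery", "vein"):
        g = pr.networks[tree].to_networkx()
        q = solution.state.x_N[pr.flow_cols[tree]]
        qmax = np.max(np.abs(q)) or 1.0
        for k, sid in enumerate(pr.networks[tree].segment_ids):
            s = pr.networks[tree].segments[sid]
            g.edges[s.node_a, s.node_b]["flow_mm3_s"] = float(q[k])
            g.edges[s.node_a, s.node_b]["width"] = float(abs(q[k]) / qmax)
        p = os.path.join(out_dir, f"{prefix}_{tree}.graphml")
        import networkx as nx
        nx.write_graphml(g, p)
        paths[f"{tree}_graphml"] = p
    return paths


def read_field_csv(path) -> np.ndarray:
    """Re-read a field CSV written by :func:`export_fields` (bit-exact)."""
    return np.loadtxt(path, delimiter=",").T
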