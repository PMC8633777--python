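"""Vascular graph model.

Arteries and veins are represented as graphs of cylindrical segments.
Each segment carries a signed volumetric flow and obeys the
Hagen–Poiseuille pressure drop, optionally augmented by a Bernoulli-type
junction loss (relative to the *datum* vessel, the one the flow
approaches the junction from) and by a pressure-dependent elastic
radius.  Mass is conserved at internal nodes; root nodes carry Dirichlet
pressure data; terminal (degree-1, non-root) nodes couple to the
capillary continuum elsewhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ROLE_ROOT = "root"
ROLE_INTERNAL = "internal"
ROLE_TERMINAL = "terminal"

TREE_ARTERY = "artery"
TREE_VEIN = "vein"

#: Elastic radius is clamped to this window around the rest radius for
#: solver robustness; physiological dilations are a few percent, so the
#: clamp is inactive in normal regimes.
RADIUS_CLAMP = (0.5, 2.0)


class NetworkError(ValueError):
    """Invalid vascular network or segment data."""


@dataclass(frozen=True)
class NodeRecord:
    """A graph node: root (inlet/outlet), internal junction, or terminal."""

    id: str
    x: float
    y: float
    role: str = ROLE_INTERNAL
    tree: str = TREE_ARTERY

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class SegmentRecord:
    """A cylindrical vessel segment between two nodes.

    ``radius`` is the rest (pressure-free) radius r_init in mm; the
    effective radius under load lives in :class:`NetworkState`.  Flow is
    signed positive in the ``node_a -> node_b`` direction.
    """

    id: str
    node_a: str
    node_b: str
    radius: float
    length: float
    tree: str = TREE_ARTERY
    wall_thickness_ratio: float = 0.22

    def __post_init__(self):
        if self.length <= 0:
            raise NetworkError(f"segment {self.id}: length must be > 0, got {self.length}")
        if self.radius <= 0:
            raise NetworkError(f"segment {self.id}: radius must be > 0, got {self.radius}")
        if not 0 < self.wall_thickness_ratio < 1:
            raise NetworkError(
                f"segment {self.id}: wall_thickness_ratio must be in (0,1), "
                f"got {self.wall_thickness_ratio}"
            )
        if self.radius >= self.length:
            warnings.warn(
                f"segment {self.id}: radius {self.radius} not << length {self.length}; "
                "the long-thin-tube assumption is questionable",
                stacklevel=2,
            )

    @property
    def r_init(self) -> float:
        return self.radius


@dataclass(frozen=True)
class FlowParameters:
    """Blood and vessel-wall material parameters (mm/s/kPa units).

    Defaults are the frog-tongue values: viscosity 3e-6 kPa·s, Young
    modulus 1 MPa for arteries and half that for veins, Poisson ratio
    0.5.  Blood density only enters the junction loss; 1050 kg/m^3.
    """

    viscosity: float = 3.0e-6          # kPa s
    density: float = 1.05e-6           # kg mm^-3
    E_artery: float = 1000.0           # kPa
    E_vein: float = 500.0              # kPa
    poisson: float = 0.5               # dimensionless

    def __post_init__(self):
        for name in ("viscosity", "density", "E_artery", "E_vein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.poisson <= 0.5:
            raise ValueError("poisson ratio must lie in [0, 0.5]")

    def youngs_modulus(self, tree: str) -> float:
        return self.E_artery if tree == TREE_ARTERY else self.E_vein


class VascularNetwork:
    """An arterial or venous vessel graph with cached index arrays."""

    def __init__(self, nodes: Iterable[NodeRecord], segments: Iterable[SegmentRecord],
                 tree: str = TREE_ARTERY, validate: bool = True):
        self.tree = tree
        self.nodes: dict[str, NodeRecord] = {n.id: n for n in nodes}
        self.segments: dict[str, SegmentRecord] = {s.id: s for s in segments}
        self.node_ids: list[str] = list(self.nodes)
        self.segment_ids: list[str] = list(self.segments)
        self._node_index = {nid: i for i, nid in enumerate(self.node_ids)}
        self._segment_index = {sid: i for i, sid in enumerate(self.segment_ids)}
        self._build_arrays()
        if validate:
            self.validate()

    # -- construction helpers -------------------------------------------------

    def _build_arrays(self):
        idx = self._node_index
        self.positions = np.array([[n.x, n.y] for n in self.nodes.values()])
        self.seg_a = np.array([idx[s.node_a] for s in self.segments.values()], dtype=int)
        self.seg_b = np.array([idx[s.node_b] for s in self.segments.values()], dtype=int)
        self.lengths = np.array([s.length for s in self.segments.values()])
        self.radii_init = np.array([s.radius for s in self.segments.values()])
        self.wall_ratios = np.array([s.wall_thickness_ratio for s in self.segments.values()])
        deg = np.zeros(len(self.node_ids), dtype=int)
        np.add.at(deg, self.seg_a, 1)
        np.add.at(deg, self.seg_b, 1)
        self.degrees = deg
        self.roles = np.array([n.role for n in self.nodes.values()])
        self.root_ids = [n.id for n in self.nodes.values() if n.role == ROLE_ROOT]
        self.terminal_ids = [n.id for n in self.nodes.values() if n.role == ROLE_TERMINAL]
        self.internal_ids = [n.id for n in self.nodes.values() if n.role == ROLE_INTERNAL]

    def node_index(self, node_id: str) -> int:
        return self._node_index[node_id]

    def segment_index(self, segment_id: str) -> int:
        return self._segment_index[segment_id]

    def incident_segments(self, node_id: str) -> list[str]:
        i = self._node_index[node_id]
        hits = np.flatnonzero((self.seg_a == i) | (self.seg_b == i))
        return [self.segment_ids[k] for k in hits]

    def root_segments(self) -> dict[str, str]:
        """Map each root node id to the id of its single incident segment."""
        return {rid: self.incident_segments(rid)[0] for rid in self.root_ids}

    def validate(self):
        if not self.root_ids:
            raise NetworkError(f"{self.tree} network has no root node")
        if not self.terminal_ids:
            raise NetworkError(f"{self.tree} network has no terminal node")
        for nid in self.root_ids + self.terminal_ids:
            d = self.degrees[self._node_index[nid]]
            if d != 1:
                raise NetworkError(f"node {nid} has role root/terminal but degree {d} != 1")
        for nid in self.internal_ids:
            d = self.degrees[self._node_index[nid]]
            if d < 2:
                raise NetworkError(f"internal node {nid} has degree {d} < 2")
        for s in self.segments.values():
            for end in (s.node_a, s.node_b):
                if end not in self.nodes:
                    raise NetworkError(f"segment {s.id} endpoint {end} is not a node")
        # Every connected component must own at least one root (pressure
        # datum) and one terminal (capillary coupling); a multi-component
        # network is legal (the capillary bed joins the pieces) but noted.
        g = self.to_networkx()
        comps = list(nx.connected_components(g))
        for comp in comps:
            roles = {self.nodes[n].role for n in comp}
            if ROLE_ROOT not in roles or ROLE_TERMINAL not in roles:
                raise NetworkError(
                    f"{self.tree} network component {sorted(comp)[:4]}... lacks a root "
                    "or a terminal; the flow problem on it is ill-posed"
                )
        if len(comps) > 1:
            log.info("%s network has %d components (joined only via the capillary bed)",
                     self.tree, len(comps))

    # -- graph views ----------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes.values():
            g.add_node(n.id, x=n.x, y=n.y, role=n.role, tree=n.tree)
        for s in self.segments.values():
            g.add_edge(s.node_a, s.node_b, id=s.id, radius_mm=s.radius,
                       length_mm=s.length, tree=s.tree,
                       wall_thickness_ratio=s.wall_thickness_ratio)
        return g

    def with_segment_radius(self, segment_id: str, radius: float) -> "VascularNetwork":
        segs = [replace(s, radius=radius) if s.id == segment_id else s
                for s in self.segments.values()]
        return VascularNetwork(self.nodes.values(), segs, tree=self.tree, validate=False)

    # -- I/O ------------------------------------------------------------------

    @classmethod
    def from_csv(cls, nodes_path, segments_path, tree: str | None = None,
                 wall_thickness_ratio: float | None = None) -> "VascularNetwork":
        """Read node/segment tables.

        ``nodes.csv``: id, x_mm, y_mm, role, tree.
        ``segments.csv``: id, node_a, node_b, radius_mm [, length_mm].
        Missing segment lengths are computed from node coordinates.
        """
        nd = pd.read_csv(nodes_path, dtype={"id": str})
        sd = pd.read_csv(segments_path, dtype={"id": str, "node_a": str, "node_b": str})
        nodes = [NodeRecord(str(r.id), float(r.x_mm), float(r.y_mm), str(r.role),
                            str(getattr(r, "tree", tree or TREE_ARTERY)))
                 for r in nd.itertuples()]
        pos = {n.id: n.position for n in nodes}
        tr = tree or nodes[0].tree
        if wall_thickness_ratio is None:
            wall_thickness_ratio = 0.22 if tr == TREE_ARTERY else 0.1
        segs = []
        for r in sd.itertuples():
            if hasattr(r, "length_mm") and not pd.isna(r.length_mm):
                length = float(r.length_mm)
            else:
                length = float(np.linalg.norm(pos[str(r.node_a)] - pos[str(r.node_b)]))
            segs.append(SegmentRecord(str(r.id), str(r.node_a), str(r.node_b),
                                      float(r.radius_mm), length, tr, wall_thickness_ratio))
        return cls(nodes, segs, tree=tr)

    def to_csv(self, nodes_path, segments_path):
        pd.DataFrame([{"id": n.id, "x_mm": n.x, "y_mm": n.y, "role": n.role, "tree": n.tree}
                      for n in self.nodes.values()]).to_csv(nodes_path, index=False)
        pd.DataFrame([{"id": s.id, "node_a": s.node_a, "node_b": s.node_b,
                       "radius_mm": s.radius, "length_mm": s.length}
                      for s in self.segments.values()]).to_csv(segments_path, index=False)

    @classmethod
    def from_graphml(cls, path, tree: str | None = None) -> "VascularNetwork":
        g = nx.read_graphml(path)
        nodes = [NodeRecord(str(n), float(d["x"]), float(d["y"]), d["role"],
                            d.get("tree", tree or TREE_ARTERY)) for n, d in g.nodes(data=True)]
        tr = tree or nodes[0].tree
        segs = [SegmentRecord(str(d["id"]), str(u), str(v), float(d["radius_mm"]),
                              float(d["length_mm"]), d.get("tree", tr),
                              float(d.get("wall_thickness_ratio", 0.22 if tr == TREE_ARTERY else 0.1)))
                for u, v, d in g.edges(data=True)]
        return cls(nodes, segs, tree=tr)

    def to_graphml(self, path):
        nx.write_graphml(self.to_networkx(), path)


@dataclass
class NetworkState:
    """Unknowns on one tree: nodal pressures (kPa), signed segment flows
    (mm^3/s, positive node_a -> node_b) and effective radii (mm)."""

    node_pressure: np.ndarray
    segment_flow: np.ndarray
    effective_radius: np.ndarray

    @classmethod
    def zeros(cls, network: VascularNetwork) -> "NetworkState":
        return cls(np.zeros(len(network.node_ids)), np.zeros(len(network.segment_ids)),
                   network.radii_init.copy())


# ---------------------------------------------------------------------------
# Per-segment physics
# ---------------------------------------------------------------------------

def poiseuille_drop(q: float, L: float, r: float, mu: float) -> float:
    """Hagen–Poiseuille pressure drop 8 mu L q / (pi r^4), sign follows q."""
    L = np.asarray(L, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(L <= 0) or np.any(r <= 0):
        raise NetworkError("poiseuille_drop requires L > 0 and r > 0")
    return 8.0 * mu * L * q / (np.pi * r**4)


def poiseuille_resistance(L, r, mu):
    """Hydraulic resistance 8 mu L / (pi r^4) of a cylindrical tube."""
    return 8.0 * mu * np.asarray(L, float) / (np.pi * np.asarray(r, float) ** 4)


def junction_drop(q_n: float, r_n: float, q_dat: float, r_dat: float,
                  theta: float, rho: float) -> float:
    """Bernoulli-type junction pressure loss relative to the datum vessel.

    The datum is the vessel the flow approaches the junction from;
    ``theta`` is the angle between datum and vessel *n* at the junction.
    Nonnegative whenever q_n/q_dat >= 0 (perfectly aligned equal tubes
    lose nothing; any radius/flow/angle mismatch costs pressure).
    """
    if q_dat == 0:
        raise NetworkError("junction_drop: datum flow must be nonzero")
    if r_n <= 0 or r_dat <= 0:
        raise NetworkError("junction_drop: radii must be positive")
    x = (q_n * r_dat**2) / (q_dat * r_n**2)
    bracket = 1.0 + x * x - 2.0 * x * np.cos(0.75 * theta)
    return rho * q_dat**2 / (2.0 * np.pi**2 * r_dat**4) * bracket


def select_datum(incident: Sequence[str], flows_into_node: Mapping[str, float]) -> str | None:
    """Pick the datum vessel at a junction: the inflowing segment with the
    largest |flow|; ties break to the lowest segment id; no inflow -> None
    (junction losses are then skipped at this node for this iterate)."""
    inflows = [(sid, flows_into_node[sid]) for sid in incident if flows_into_node[sid] > 0]
    if not inflows:
        return None
    return min(inflows, key=lambda t: (-abs(t[1]), t[0]))[0]


def elastic_radius(r_init, h_ratio, E, poisson, p_in, p_ext):
    """Pressure-loaded vessel radius from thin-wall elasticity.

    r = r_init + (1 - lambda^2) r_init^2 / (h E) * (P_in - P_ext), with
    wall thickness h = h_ratio * r_init.  P_in is the mean of the
    segment's endpoint pressures, P_ext the capillary pressure at the
    segment midpoint.  Clamped to [0.5, 2] x r_init for robustness.
    """
    r_init = np.asarray(r_init, dtype=float)
    h = h_ratio * r_init
    r = r_init + (1.0 - poisson**2) * r_init**2 / (h * E) * (np.asarray(p_in) - np.asarray(p_ext))
    lo, hi = RADIUS_CLAMP[0] * r_init, RADIUS_CLAMP[1] * r_init
    clipped = np.clip(r, lo, hi)
    n_clamped = np.count_nonzero(clipped != r)
    if n_clamped:
        log.debug("elastic_radius: clamped %d radii to [0.5, 2] x r_init", n_clamped)
    return clipped


@dataclass(frozen=True)
class ModelVariant:
    """Which nonlinearities are active.  The four combinations are the
    named models: baseline (both), junction (no elasticity), elasticity
    (no junction losses), linear (neither)."""

    junction_enabled: bool = True
    elasticity_enabled: bool = True

    @classmethod
    def from_name(cls, name: str) -> "ModelVariant":
        table = {
            "baseline": cls(True, True),
            "junction": cls(True, False),
            "elasticity": cls(False, True),
            "linear": cls(False, False),
        }
        try:
            return table[name]
        except KeyError:
            raise ValueError(f"unknown model variant {name!r}; choose from {sorted(table)}")

    @property
    def name(self) -> str:
        return {(True, True): "baseline", (True, False): "junction",
                (False, True): "elasticity", (False, False): "linear"}[
                    (self.junction_enabled, self.elasticity_enabled)]

    @property
    def is_linear(self) -> bool:
        return not (self.junction_enabled or self.elasticity_enabled)


def junction_angle(network: VascularNetwork, node_id: str, seg_datum: str, seg_n: str,
                   flow_datum: float, flow_n: float) -> float:
    """Angle in [0, pi] between the datum's flow direction entering the
    junction and segment n's flow direction there (0 = straight through)."""
    ni = network.node_index(node_id)

    def flow_dir(sid: str, q: float) -> np.ndarray:
        k = network.segment_index(sid)
        a, b = network.seg_a[k], network.seg_b[k]
        d = network.positions[b] - network.positions[a]
        nrm = np.linalg.norm(d)
        d = d / nrm if nrm > 0 else d
        return d if q >= 0 else -d

    d_dat = flow_dir(seg_datum, flow_datum)
    d_n = flow_dir(seg_n, flow_n)
    c = float(np.clip(np.dot(d_dat, d_n), -1.0, 1.0))
    return float(np.arccos(c))


def _junction_nodes(network: VascularNetwork) -> list[str]:
    return [nid for nid in network.internal_ids
            if network.degrees[network.node_index(nid)] >= 3]


def junction_drops(network: VascularNetwork, state: NetworkState,
                   params: FlowParameters) -> np.ndarray:
    """Per-segment junction loss magnitude (kPa), summed over the
    segment's endpoint junctions where it is not the datum vessel."""
    drops = np.zeros(len(network.segment_ids))
    q = state.segment_flow
    r = state.effective_radius
    for nid in _junction_nodes(network):
        incident = network.incident_segments(nid)
        ni = network.node_index(nid)
        into = {}
        for sid in incident:
            k = network.segment_index(sid)
            s = 1.0 if network.seg_b[k] == ni else -1.0
            into[sid] = s * q[k]
        datum = select_datum(incident, into)
        if datum is None:
            continue
        kd = network.segment_index(datum)
        q_dat, r_dat = abs(q[kd]), r[kd]
        if q_dat == 0:
            continue
        for sid in incident:
            if sid == datum:
                continue
            k = network.segment_index(sid)
            if q[k] == 0:
                continue
            theta = junction_angle(network, nid, datum, sid, q[kd], q[k])
            drops[k] += junction_drop(abs(q[k]), r[k], q_dat, r_dat, theta, params.density)
    return drops


def total_segment_drop(network: VascularNetwork, segment_id: str, state: NetworkState,
                       params: FlowParameters, variant: ModelVariant) -> float:
    """Total signed pressure drop along a segment in the node_a -> node_b
    direction: Poiseuille part plus (when enabled) junction losses at its
    endpoint junctions, applied in the direction of flow."""
    k = network.segment_index(segment_id)
    r = state.effective_radius if variant.elasticity_enabled else network.radii_init
    q = state.segment_flow[k]
    drop = poiseuille_drop(q, network.lengths[k], r[k], params.viscosity)
    if variant.junction_enabled:
        st = NetworkState(state.node_pressure, state.segment_flow, r)
        drop += np.sign(q) * junction_drops(network, st, params)[k]
    return float(drop)


def network_residuals(network: VascularNetwork, state: NetworkState, params: FlowParameters,
                      bc: Mapping[str, float], variant: ModelVariant,
                      terminal_pressure: Mapping[str, float] | None = None) -> np.ndarray:
    """Residuals of the standalone tree equations.

    One per segment (endpoint pressure difference minus total drop), one
    per internal node (net inflow), one per root (pressure minus its
    Dirichlet datum).  Terminal pressures are either taken from
    ``state.node_pressure`` or overridden via ``terminal_pressure``
    (they are coupling unknowns in the full model).  All vanish exactly
    at a solution.
    """
    p = state.node_pressure.copy()
    if terminal_pressure:
        for tid, val in terminal_pressure.items():
            p[network.node_index(tid)] = val
    q = state.segment_flow
    r = state.effective_radius if variant.elasticity_enabled else network.radii_init
    if len(p) != len(network.node_ids) or len(q) != len(network.segment_ids):
        raise NetworkError("state arrays do not match network dimensions")

    drop = poiseuille_drop(q, network.lengths, r, params.viscosity)
    if variant.junction_enabled:
        st = NetworkState(p, q, np.asarray(r, float))
        drop = drop + np.sign(q) * junction_drops(network, st, params)
    res_seg = p[network.seg_a] - p[network.seg_b] - drop

    net_in = np.zeros(len(network.node_ids))
    np.add.at(net_in, network.seg_b, q)
    np.add.at(net_in, network.seg_a, -q)
    res_node = np.array([net_in[network.node_index(nid)] for nid in network.internal_ids])

    res_root = np.array([p[network.node_index(rid)] - bc[rid] for rid in network.root_ids])
    return np.concatenate([res_seg, res_node, res_root])
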