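"""Synthetic paired vasculatures, organ masks, fixtures and occlusions.

The generator emulates the geometry class of a flat, hand-traced organ
vasculature: per tree (artery and vein) two root vessels enter from the
lower boundary and branch dyadically toward interior terminals whose
radii approach the raster pixel scale.  Child radii follow a Murray-type
rule r_parent^gamma = sum r_child^gamma (gamma = 3 by default).  The two
arterial sub-networks may be joined near the top of the domain by a
small connecting vessel and the venous ones near the middle by a large
one (anastomoses), which is what gives the venous side its collateral
drainage.  The construction is a stand-in for real segmented anatomy:
it reproduces topology and scaling, not any particular organ's shape.

All randomness flows from the spec's seed; the same seed reproduces the
same networks bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import StructuredGrid
from .network import (NodeRecord, SegmentRecord, VascularNetwork,
                      ROLE_INTERNAL, ROLE_ROOT, ROLE_TERMINAL, TREE_ARTERY, TREE_VEIN)


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class TreeSpec:
    """Study-condition parameters for a paired synthetic vasculature."""

    width: float = 8.0            # mm
    height: float = 8.0           # mm
    dx: float = 0.5               # mm; 16x16 cells for the defaults
    depth: int = 3                # branching generations below the trunk
    root_radius: float = 0.25     # mm
    murray_gamma: float = 3.0
    branch_angle: float = 0.55    # rad, half-opening of a split
    angle_jitter: float = 0.15    # rad, uniform jitter from the seed
    length_decay: float = 0.72
    trunk_length_frac: float = 0.22   # of domain height
    seed: int = 0
    artery_anastomosis: bool = True
    vein_anastomosis: bool = True
    vein_minor_scale: float = 0.75    # radius scale of the minor venous root
    anastomosis_radius_frac_artery: float = 0.4   # "small vessel", x root radius
    anastomosis_radius_frac_vein: float = 0.8     # "big vessel", x root radius

    def __post_init__(self):
        if self.depth < 1:
            raise GenerationError("depth must be >= 1")
        if (self.artery_anastomosis or self.vein_anastomosis) and self.depth < 2:
            raise GenerationError("anastomoses require depth >= 2 "
                                  "(a leaf of each sub-tree is consumed)")


@dataclass(frozen=True)
class OcclusionSpec:
    """Partial occlusion: remove ``rate`` of the segment's rest radius."""

    segment_id: str
    rate: float

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise GenerationError(f"occlusion rate must be in [0, 1], got {self.rate}")


#: rate=1 keeps the segment with this fraction of its radius instead of
#: deleting it, so solver dimensions are occlusion-invariant.
OCCLUSION_RADIUS_FLOOR = 1e-3


def apply_occlusion(network: VascularNetwork, spec: OcclusionSpec) -> VascularNetwork:
    """Copy of ``network`` with the target's rest radius scaled by (1-rate),
    floored at a tiny fraction of the original for full occlusion."""
    if spec.segment_id not in network.segments:
        raise GenerationError(f"unknown segment id {spec.segment_id!r}")
    r0 = network.segments[spec.segment_id].radius
    r = max((1.0 - spec.rate) * r0, OCCLUSION_RADIUS_FLOOR * r0)
    return network.with_segment_radius(spec.segment_id, r)


def _grow_subtree(rng, nodes, segs, prefix, root_xy, root_radius, spec, tree,
                  wall_ratio, margin, lean=0.0):
    """Grow one dyadic sub-tree from a boundary root; returns leaf node ids."""
    w, h = spec.width, spec.height

    def clamp(p):
        return np.array([np.clip(p[0], margin, w - margin),
                         np.clip(p[1], margin, h - margin)])

    nodes.append(NodeRecord(f"{prefix}r", root_xy[0], root_xy[1], ROLE_ROOT, tree))
    trunk_len = spec.trunk_length_frac * h
    direction = np.array([np.sin(lean), np.cos(lean)])  # mostly upward
    tip = clamp(np.asarray(root_xy) + trunk_len * direction)
    nodes.append(NodeRecord(f"{prefix}t", tip[0], tip[1], ROLE_INTERNAL, tree))
    segs.append(SegmentRecord(f"{prefix}trunk", f"{prefix}r", f"{prefix}t", root_radius,
                              float(np.linalg.norm(tip - np.asarray(root_xy))),
                              tree, wall_ratio))
    frontier = [(f"{prefix}t", tip, direction, root_radius, trunk_len)]
    leaves = []
    child_factor = 2.0 ** (-1.0 / spec.murray_gamma)
    for gen in range(spec.depth):
        nxt = []
        for bi, (nid, pos, d, r, L) in enumerate(frontier):
            phi = np.arctan2(d[0], d[1])
            for side, s in (("L", -1.0), ("R", 1.0)):
                ang = phi + s * spec.branch_angle + rng.uniform(-1, 1) * spec.angle_jitter
                newd = np.array([np.sin(ang), np.cos(ang)])
                newL = L * spec.length_decay
                child = clamp(pos + newL * newd)
                if np.linalg.norm(child - pos) < 0.5 * newL:
                    # the clamp squeezed the branch against the margin box:
                    # grow toward the domain centre instead
                    centre = np.array([w / 2, h / 2])
                    to_c = centre - pos
                    nc = np.linalg.norm(to_c)
                    if nc < 1e-9:
                        raise GenerationError(
                            "sub-tree does not fit in the domain; reduce depth or lengths")
                    child = clamp(pos + newL * to_c / nc)
                if np.linalg.norm(child - pos) < 0.25 * newL:
                    raise GenerationError(
                        "sub-tree does not fit in the domain; reduce depth or lengths")
                cid = f"{nid}{side}"
                role = ROLE_TERMINAL if gen == spec.depth - 1 else ROLE_INTERNAL
                nodes.append(NodeRecord(cid, child[0], child[1], role, tree))
                segs.append(SegmentRecord(f"s{cid}", nid, cid, r * child_factor,
                                          float(np.linalg.norm(child - pos)),
                                          tree, wall_ratio))
                nxt.append((cid, child, newd, r * child_factor, newL))
                if role == ROLE_TERMINAL:
                    leaves.append(cid)
        frontier = nxt
    return leaves


def _connect(nodes, segs, id_a, id_b, seg_id, radius, tree, wall_ratio):
    pos = {n.id: n.position for n in nodes}
    L = float(np.linalg.norm(pos[id_a] - pos[id_b]))
    if L <= 0:
        raise GenerationError("anastomosis endpoints coincide")
    segs.append(SegmentRecord(seg_id, id_a, id_b, radius, L, tree, wall_ratio))


def _finalize_roles(nodes, segs):
    """Recompute roles from degree: anastomoses turn leaves internal."""
    deg = {}
    for s in segs:
        deg[s.node_a] = deg.get(s.node_a, 0) + 1
        deg[s.node_b] = deg.get(s.node_b, 0) + 1
    out = []
    for n in nodes:
        if n.role == ROLE_ROOT:
            out.append(n)
        else:
            role = ROLE_TERMINAL if deg.get(n.id, 0) == 1 else ROLE_INTERNAL
            out.append(replace(n, role=role))
    return out


def generate_paired_networks(spec: TreeSpec) -> tuple[VascularNetwork, VascularNetwork,
                                                      StructuredGrid]:
    """Deterministically generate (arterial network, venous network, mask).

    Arterial roots enter left-of-centre on the lower boundary, venous
    roots right-of-centre (mirrored organ layout).  Terminals keep at
    least the default mollifier radius (3 cells) of clearance from the
    mask boundary.
    """
    rng = np.random.default_rng(spec.seed)
    nx_cells = round(spec.width / spec.dx)
    ny_cells = round(spec.height / spec.dx)
    grid = StructuredGrid.full(nx_cells, ny_cells, spec.dx)
    margin = 3.0 * spec.dx + 0.5 * spec.dx
    if margin * 2 >= min(spec.width, spec.height):
        raise GenerationError("domain too small for terminal clearance margin")

    nets = {}
    for tree, xs, wall in ((TREE_ARTERY, (0.20, 0.42), 0.22),
                           (TREE_VEIN, (0.58, 0.80), 0.1)):
        nodes, segs = [], []
        leaves = {}
        for i, xf in enumerate(xs):
            scale = 1.0
            if tree == TREE_VEIN and i == 0:
                scale = spec.vein_minor_scale  # left venous root is the minor one
            lean = rng.uniform(-0.2, 0.2)
            leaves[i] = _grow_subtree(rng, nodes, segs, f"{tree[0]}{i}_",
                                      (xf * spec.width, 0.0),
                                      spec.root_radius * scale, spec, tree, wall,
                                      margin, lean)
        want = spec.artery_anastomosis if tree == TREE_ARTERY else spec.vein_anastomosis
        if want:
            pos = {n.id: n.position for n in nodes}
            if tree == TREE_ARTERY:
                # connect near-top leaves of the two sub-trees by a small vessel
                score = {i: sorted(leaves[i], key=lambda nid: -pos[nid][1])
                         for i in leaves}
                radius = spec.anastomosis_radius_frac_artery * spec.root_radius
            else:
                # connect near-mid-height leaves by a large vessel
                mid = spec.height / 2
                score = {i: sorted(leaves[i], key=lambda nid: abs(pos[nid][1] - mid))
                         for i in leaves}
                radius = spec.anastomosis_radius_frac_vein * spec.root_radius
            # among the best few candidates per side, prefer the highest-ranked
            # pair that is not degenerately short for a vessel of this radius
            min_len = 5.0 * radius
            pairs = [(a, b) for a in score[0][:3] for b in score[1][:3]]
            ok = [p for p in pairs
                  if np.linalg.norm(pos[p[0]] - pos[p[1]]) >= min_len]
            a, b = ok[0] if ok else max(
                pairs, key=lambda p: np.linalg.norm(pos[p[0]] - pos[p[1]]))
            _connect(nodes, segs, a, b, f"{tree[0]}_anastomosis", radius, tree, wall)
        nodes = _finalize_roles(nodes, segs)
        nets[tree] = VascularNetwork(nodes, segs, tree=tree)
    return nets[TREE_ARTERY], nets[TREE_VEIN], grid


# ---------------------------------------------------------------------------
# Named fixtures with analytic or oracle expectations
# ---------------------------------------------------------------------------

def fixture_single_tube(length: float = 2.0, radius: float = 0.1,
                        tree: str = TREE_ARTERY) -> VascularNetwork:
    """One root -> terminal segment; pure Poiseuille, closed form."""
    wall = 0.22 if tree == TREE_ARTERY else 0.1
    nodes = [NodeRecord("root", 0.0, 0.0, ROLE_ROOT, tree),
             NodeRecord("tip", length, 0.0, ROLE_TERMINAL, tree)]
    segs = [SegmentRecord("tube", "root", "tip", radius, length, tree, wall)]
    return VascularNetwork(nodes, segs, tree=tree)


def fixture_y_bifurcation(parent_radius: float = 0.1) -> VascularNetwork:
    """Root -> junction -> two terminals, Murray gamma=3 child radii,
    printed 2D angles; the smallest junction-loss test case."""
    rc = parent_radius * 2.0 ** (-1.0 / 3.0)
    nodes = [NodeRecord("root", 0.0, 0.0, ROLE_ROOT, TREE_ARTERY),
             NodeRecord("j", 1.0, 0.0, ROLE_INTERNAL, TREE_ARTERY),
             NodeRecord("t1", 2.0, 0.6, ROLE_TERMINAL, TREE_ARTERY),
             NodeRecord("t2", 2.0, -0.6, ROLE_TERMINAL, TREE_ARTERY)]
    L_child = float(np.hypot(1.0, 0.6))
    segs = [SegmentRecord("parent", "root", "j", parent_radius, 1.0, TREE_ARTERY, 0.22),
            SegmentRecord("child1", "j", "t1", rc, L_child, TREE_ARTERY, 0.22),
            SegmentRecord("child2", "j", "t2", rc, L_child, TREE_ARTERY, 0.22)]
    return VascularNetwork(nodes, segs, tree=TREE_ARTERY)


def fixture_minimal_loop() -> tuple[VascularNetwork, VascularNetwork, StructuredGrid]:
    """One artery segment -> 1-cell two-compartment bed -> one vein segment.

    Both terminals sit at the single cell's centre, so each mollifier is
    the degenerate weight-1 bump with m=1 and the whole solve is the
    series circuit Q = (P_in-P_out)/(R1 + kappa_a + 1/(alpha V) + kappa_v + R2).
    """
    grid = StructuredGrid.full(1, 1, 1.0)
    art = VascularNetwork(
        [NodeRecord("a_root", -0.5, 0.5, ROLE_ROOT, TREE_ARTERY),
         NodeRecord("a_tip", 0.5, 0.5, ROLE_TERMINAL, TREE_ARTERY)],
        [SegmentRecord("a_seg", "a_root", "a_tip", 0.05, 1.0, TREE_ARTERY, 0.22)],
        tree=TREE_ARTERY)
    ven = VascularNetwork(
        [NodeRecord("v_root", 1.5, 0.5, ROLE_ROOT, TREE_VEIN),
         NodeRecord("v_tip", 0.5, 0.5, ROLE_TERMINAL, TREE_VEIN)],
        [SegmentRecord("v_seg", "v_root", "v_tip", 0.06, 1.0, TREE_VEIN, 0.1)],
        tree=TREE_VEIN)
    return art, ven, grid


def fixture_mini_organ(seed: int = 7) -> tuple[VascularNetwork, VascularNetwork,
                                               StructuredGrid, TreeSpec]:
    """The 16x16-cell two-tree mini organ used throughout the tests."""
    spec = TreeSpec(seed=seed)
    art, ven, grid = generate_paired_networks(spec)
    return art, ven, grid, spec


def fixtures() -> dict[str, object]:
    """All named small instances, keyed by name."""
    return {
        "single_tube": fixture_single_tube(),
        "y_bifurcation": fixture_y_bifurcation(),
        "minimal_loop": fixture_minimal_loop(),
        "mini_organ": fixture_mini_organ(),
    }
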