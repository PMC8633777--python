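"""YAML/JSON run configuration.

Pressures cross this boundary in mmHg; radii and lengths in mm; the
remaining physical parameters in the internal mm/s/kPa units (the
perfusion coefficient's customary kg^-1 mm s is numerically identical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

from .darcy import CapillaryParameters
from .grid import StructuredGrid
from .network import FlowParameters, VascularNetwork
from .solver import BoundaryConditions, SolverSettings
from .synthetic import TreeSpec, fixture_mini_organ, generate_paired_networks
from .units import mmhg_to_kpa

DEFAULT_PRESSURES_MMHG = {"artery_inlet": 30.0, "vein_outlet": 7.5}


@dataclass
class RunConfig:
    network_artery: VascularNetwork
    network_vein: VascularNetwork
    grid: StructuredGrid
    flow: FlowParameters
    capillary: CapillaryParameters
    bc: BoundaryConditions
    settings: SolverSettings
    variant: str = "baseline"
    raw: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        if str(path).endswith(".json"):
            cfg = json.load(fh)
        else:
            cfg = yaml.safe_load(fh)
    return build_config(cfg)


def build_config(cfg: dict) -> RunConfig:
    net = cfg.get("network", {"synthetic": {}})
    if "files" in net:
        f = net["files"]
        art = VascularNetwork.from_csv(f["nodes_artery"], f["segments_artery"], tree="artery")
        ven = VascularNetwork.from_csv(f["nodes_vein"], f["segments_vein"], tree="vein")
        dx = float(f["dx_mm"])
        if str(f["mask"]).endswith(".pgm"):
            grid = StructuredGrid.from_pgm(f["mask"], dx)
        else:
            grid = StructuredGrid.from_csv(f["mask"], dx)
    elif "synthetic" in net:
        spec = TreeSpec(**net["synthetic"])
        art, ven, grid = generate_paired_networks(spec)
    else:
        art, ven, grid, _ = fixture_mini_organ()

    pressures = {**DEFAULT_PRESSURES_MMHG, **cfg.get("pressures_mmHg", {})}
    bc = BoundaryConditions(mmhg_to_kpa(pressures["artery_inlet"]),
                            mmhg_to_kpa(pressures["vein_outlet"]))
    flow = FlowParameters(**cfg.get("flow_parameters", {}))
    capillary = CapillaryParameters(**cfg.get("capillary_parameters", {}))
    settings = SolverSettings(**cfg.get("solver", {}))
    return RunConfig(art, ven, grid, flow, capillary, bc, settings,
                     variant=cfg.get("variant", "baseline"), raw=cfg)
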