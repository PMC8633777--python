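"""Terminal-to-continuum coupling.

Each terminal node of a vessel tree injects (artery) or withdraws
(vein) flow from its Darcy compartment.  A point source would be a
Dirac singularity, so the flow is spread by a compactly supported bump
(mollifier) of radius epsilon, discretely normalized over the in-mask
support.  Pressure continuity is imposed through a lumped capillary
resistance kappa: the Poiseuille resistance of a surrogate tube of
length epsilon and radius m^(-1/3) * r_t, m being the number of cells in
the support.

Sign convention, used everywhere: Q_t is the flow arriving at the
terminal node through its segment, which equals the signed source
strength delivered into the compartment — positive for arterial
terminals, negative for venous ones in normal operation.  With this
convention the pressure-continuity residual

    P_t - sum_i w_i P_beta,i - kappa * Q_t

holds for both trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import StructuredGrid
from .network import VascularNetwork


class CouplingError(ValueError):
    pass


@dataclass
class Mollifier:
    """Discrete bump: nonnegative weights on in-mask cells, summing to 1."""

    center: np.ndarray
    epsilon: float
    cells: np.ndarray    # compact cell indices of the support
    weights: np.ndarray  # same length, sum == 1


@dataclass
class TerminalCoupling:
    terminal_id: str
    compartment: str          # "artery" | "vein"
    segment_index: int        # index of the terminal's segment in its network
    flow_sign: float          # +1 if terminal is node_b of the segment else -1
    r_t: float                # terminal segment radius (mm)
    mollifier: Mollifier
    m: int                    # cells within the epsilon-disc
    kappa: float              # kPa s mm^-3

    def __post_init__(self):
        if self.m < 1:
            raise CouplingError(f"terminal {self.terminal_id}: empty mollifier support")
        if self.kappa <= 0:
            raise CouplingError(f"terminal {self.terminal_id}: kappa must be positive")


def mollifier_weights(grid: StructuredGrid, center, epsilon: float,
                      terminal_id: str = "?") -> Mollifier:
    """Bump weights w_i ∝ exp(-1/(1 - d_i^2/eps^2)) on in-mask cells with
    centre distance d_i < epsilon, renormalized to sum exactly to 1.

    Renormalization (rather than a continuum normalization constant)
    guarantees exact discrete mass transfer even when the support is
    clipped by the organ boundary.
    """
    if epsilon <= 0:
        raise CouplingError("epsilon must be positive")
    center = np.asarray(center, dtype=float)
    cells = grid.cells_within(center, epsilon)
    if len(cells) == 0:
        # degenerate support: fall back to the single nearest in-mask cell
        # if the terminal at least sits inside the grid near the mask
        c = grid.cell_at(center)
        if c < 0:
            raise CouplingError(
                f"terminal {terminal_id}: no in-mask cell within epsilon={epsilon} "
                f"of {tuple(center)}"
            )
        cells = np.array([c])
        return Mollifier(center, epsilon, cells, np.array([1.0]))
    d = np.linalg.norm(grid.cell_centers[cells] - center, axis=1)
    u = d / epsilon
    w = np.exp(-1.0 / (1.0 - u * u))
    w = w / w.sum()
    return Mollifier(center, epsilon, cells, w)


def kappa(mu: float, epsilon: float, r_t: float, m: int) -> float:
    """Lumped capillary resistance around a terminal:
    kappa = 8 mu eps m^(4/3) / (pi r_t^4), the Poiseuille resistance of a
    tube of length epsilon and radius m^(-1/3) r_t."""
    if mu <= 0 or epsilon <= 0 or r_t <= 0 or m < 1:
        raise CouplingError("kappa: all arguments must be positive")
    return 8.0 * mu * epsilon * m ** (4.0 / 3.0) / (np.pi * r_t**4)


def build_couplings(network: VascularNetwork, grid: StructuredGrid, mu: float,
                    epsilon: float | None = None,
                    epsilon_overrides: dict[str, float] | None = None) -> list[TerminalCoupling]:
    """One coupling per terminal of ``network``.  Default epsilon is three
    grid cells; per-terminal overrides are allowed."""
    eps_default = 3.0 * grid.dx if epsilon is None else epsilon
    overrides = epsilon_overrides or {}
    out = []
    for tid in network.terminal_ids:
        eps = overrides.get(tid, eps_default)
        node = network.nodes[tid]
        sid = network.incident_segments(tid)[0]
        k = network.segment_index(sid)
        sign = 1.0 if network.seg_b[k] == network.node_index(tid) else -1.0
        mol = mollifier_weights(grid, node.position, eps, terminal_id=tid)
        m = max(1, len(grid.cells_within(node.position, eps)))
        r_t = network.radii_init[k]
        out.append(TerminalCoupling(tid, network.tree, k, sign, r_t, mol, m,
                                    kappa(mu, eps, r_t, m)))
    return out


def coupling_residuals(terminal_pressure: np.ndarray, terminal_flow: np.ndarray,
                       field_pressure: np.ndarray,
                       couplings: list[TerminalCoupling]) -> np.ndarray:
    """Pressure-continuity residual per terminal:
    P_t - sum_i w_i P_beta,i - kappa * Q_t, with Q_t the signed source
    strength into the compartment."""
    res = np.empty(len(couplings))
    for t, c in enumerate(couplings):
        pbar = float(c.mollifier.weights @ field_pressure[c.mollifier.cells])
        res[t] = terminal_pressure[t] - pbar - c.kappa * terminal_flow[t]
    return res


def coupling_table(couplings: list[TerminalCoupling]) -> pd.DataFrame:
    """Inspection table: terminal id, compartment, m, kappa, support size."""
    return pd.DataFrame([{
        "terminal_id": c.terminal_id,
        "compartment": c.compartment,
        "m": c.m,
        "kappa_kPa_s_mm3": c.kappa,
        "support_cells": len(c.mollifier.cells),
    } for c in couplings])
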