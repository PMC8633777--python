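"""Two-compartment Darcy capillary bed, discretized by TPFA.

The unresolved microvasculature is a homogeneous isotropic porous
medium occupying the organ mask twice over: an arterial compartment
(permeability K_a) and a venous one (K_v), exchanging fluid at rate
alpha*(P_a - P_v) per unit volume — the perfusion.  The two-point flux
approximation is consistent and convergent on the uniform grids used
here.  Discretely, all sources and exchanges are bookkept as volumetric
flows per cell (densities multiplied by cell volume) so that global
balances are plain sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .grid import StructuredGrid


@dataclass(frozen=True)
class CapillaryParameters:
    """Porous-medium parameters (mm/s/kPa units).

    alpha is the perfusion coefficient per unit volume and transmural
    pressure; its customary unit kg^-1 mm s is numerically identical to
    kPa^-1 s^-1 in this unit system.
    """

    K_artery: float = 3.0e-6      # mm^2
    K_vein: float = 6.0e-6        # mm^2
    alpha: float = 5.0e-4         # kPa^-1 s^-1
    porosity: float = 0.1         # dimensionless

    def __post_init__(self):
        for name in ("K_artery", "K_vein", "alpha", "porosity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.porosity > 1:
            raise ValueError("porosity must lie in (0, 1]")

    def permeability(self, compartment: str) -> float:
        return self.K_artery if compartment == "artery" else self.K_vein


@dataclass
class DarcyField:
    """Compact per-cell pressures (kPa) for both compartments."""

    P_artery: np.ndarray
    P_vein: np.ndarray


def transmissibility(S: float, K: float, mu: float, dx: float) -> float:
    """Face transmissibility tau = S*K/(mu*dx) (mm^3 s^-1 kPa^-1).

    This is the homogeneous-medium simplification of the harmonic-mean
    two-point transmissibility; it is symmetric in the cell pair.
    """
    return S * K / (mu * dx)


def harmonic_transmissibility(S, dx_i, mu_i, K_i, dx_j, mu_j, K_j) -> float:
    """General two-point form 2S/(dx_i mu_i / K_i + dx_j mu_j / K_j)."""
    return 2.0 * S / (dx_i * mu_i / K_i + dx_j * mu_j / K_j)


def assemble_tpfa(grid: StructuredGrid, K: float, mu: float) -> sp.csr_matrix:
    """TPFA diffusion operator over in-mask cells.

    Row i: diagonal sum of face transmissibilities, off-diagonal -tau.
    Symmetric with zero row sums (pure Neumann: constants are in the
    nullspace until sources pin the level).
    """
    tau = transmissibility(grid.face_area, K, mu, grid.dx)
    n = grid.n_cells
    f = grid.faces
    if len(f) == 0:
        return sp.csr_matrix((n, n))
    i, j = f[:, 0], f[:, 1]
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([-tau * np.ones(2 * len(f)), tau * np.ones(2 * len(f))])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def perfusion_exchange(P_artery: np.ndarray, P_vein: np.ndarray, alpha: float,
                       cell_volume: float) -> np.ndarray:
    """Per-cell volumetric exchange flow alpha*(P_a - P_v)*V_cell (mm^3/s).

    Positive = the arterial compartment loses to the venous one.
    """
    return alpha * (np.asarray(P_artery) - np.asarray(P_vein)) * cell_volume


def darcy_flux(P: np.ndarray, grid: StructuredGrid, K: float, mu: float) -> np.ndarray:
    """Per-face volumetric flux tau*(P_i - P_j) for the grid's face list;
    antisymmetric under swapping the face's cell pair."""
    tau = transmissibility(grid.face_area, K, mu, grid.dx)
    f = grid.faces
    return tau * (P[f[:, 0]] - P[f[:, 1]])


def interstitial_velocity(face_flux, S: float, porosity: float):
    """Average fluid (pore) velocity: volumetric flux / (S * porosity)."""
    if S <= 0 or porosity <= 0:
        raise ValueError("face area and porosity must be positive")
    return np.asarray(face_flux, float) / (S * porosity)


def estimate_permeability(v: float, mu: float, dP: float, dL: float) -> float:
    """Scalar-Darcy permeability estimate K = v*mu*dL/dP from a velocity
    observed across a pressure drop dP over distance dL."""
    if dP == 0:
        raise ValueError("estimate_permeability: dP must be nonzero")
    return v * mu * dL / dP
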