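"""Masked uniform grid for the capillary continuum.

The organ is rasterized on a uniform 2D cell grid with unit out-of-plane
thickness.  Faces exist only between two in-organ neighbours; the
no-flow (Neumann) outer boundary arises simply by face omission.
Raster I/O: any nonzero cell is in-organ.  CSV/PGM rasters are
row-major with row index = y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class GridError(ValueError):
    pass


@dataclass
class StructuredGrid:
    """Uniform 2D cell grid, ``mask[ix, iy]`` with x = (ix+0.5)*dx."""

    nx: int
    ny: int
    dx: float
    mask: np.ndarray
    thickness: float = 1.0

    def __post_init__(self):
        if self.dx <= 0 or self.thickness <= 0:
            raise GridError("dx and thickness must be positive")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.nx, self.ny):
            raise GridError(f"mask shape {self.mask.shape} != ({self.nx}, {self.ny})")
        if not self.mask.any():
            raise GridError("mask is empty: no in-organ cell")
        # compact index over in-mask cells
        self.cell_index = -np.ones((self.nx, self.ny), dtype=int)
        ii, jj = np.nonzero(self.mask)
        self.cell_index[ii, jj] = np.arange(len(ii))
        self.cells_ij = np.column_stack([ii, jj])
        self.n_cells = len(ii)
        self._faces = self._build_faces()
        self._tree = cKDTree(self.cell_centers)

    @classmethod
    def full(cls, nx: int, ny: int, dx: float, thickness: float = 1.0) -> "StructuredGrid":
        return cls(nx, ny, dx, np.ones((nx, ny), dtype=bool), thickness)

    def _build_faces(self) -> np.ndarray:
        pairs = []
        idx = self.cell_index
        a = idx[:-1, :]; b = idx[1:, :]
        ok = (a >= 0) & (b >= 0)
        pairs.append(np.column_stack([a[ok], b[ok]]))
        a = idx[:, :-1]; b = idx[:, 1:]
        ok = (a >= 0) & (b >= 0)
        pairs.append(np.column_stack([a[ok], b[ok]]))
        return np.vstack(pairs) if pairs else np.empty((0, 2), int)

    # -- geometry -------------------------------------------------------------

    @property
    def faces(self) -> np.ndarray:
        """(n_faces, 2) compact cell-index pairs between in-mask neighbours."""
        return self._faces

    @property
    def face_area(self) -> float:
        """Face area S = dx * thickness (mm^2), equal for all faces."""
        return self.dx * self.thickness

    @property
    def cell_volume(self) -> float:
        return self.dx**2 * self.thickness

    @property
    def cell_centers(self) -> np.ndarray:
        return (self.cells_ij + 0.5) * self.dx

    @property
    def extent(self) -> tuple[float, float]:
        return self.nx * self.dx, self.ny * self.dx

    def cell_at(self, point) -> int:
        """Compact index of the in-mask cell containing ``point``; -1 if the
        containing raster cell is outside the mask or the grid."""
        i = int(np.floor(point[0] / self.dx))
        j = int(np.floor(point[1] / self.dx))
        if not (0 <= i < self.nx and 0 <= j < self.ny):
            return -1
        return int(self.cell_index[i, j])

    def nearest_cell(self, point) -> int:
        """Compact index of the nearest in-mask cell centre."""
        c = self.cell_at(point)
        if c >= 0:
            return c
        _, k = self._tree.query(np.asarray(point, float))
        return int(k)

    def cells_within(self, center, radius: float) -> np.ndarray:
        """Compact indices of in-mask cells whose centres lie strictly
        within ``radius`` of ``center``."""
        d = np.linalg.norm(self.cell_centers - np.asarray(center, float), axis=1)
        return np.flatnonzero(d < radius)

    def scatter(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Expand a compact per-cell vector to a full (nx, ny) array."""
        out = np.full((self.nx, self.ny), fill, dtype=float)
        out[self.mask] = values
        return out

    # -- raster I/O -----------------------------------------------------------

    @classmethod
    def from_raster(cls, array: np.ndarray, dx: float, thickness: float = 1.0) -> "StructuredGrid":
        """Build from a row-major raster (row = y index): nonzero = in-organ."""
        arr = np.asarray(array)
        mask = (arr != 0).T  # (row=y, col=x) -> mask[ix, iy]
        return cls(mask.shape[0], mask.shape[1], dx, mask, thickness)

    @classmethod
    def from_csv(cls, path, dx: float, thickness: float = 1.0) -> "StructuredGrid":
        return cls.from_raster(np.loadtxt(path, delimiter=","), dx, thickness)

    @classmethod
    def from_pgm(cls, path, dx: float, thickness: float = 1.0) -> "StructuredGrid":
        return cls.from_raster(read_pgm(path), dx, thickness)

    def mask_to_csv(self, path):
        np.savetxt(path, self.mask.T.astype(int), fmt="%d", delimiter=",")

    def mask_to_pgm(self, path):
        write_pgm(path, self.mask.T.astype(np.uint8))


def read_pgm(path) -> np.ndarray:
    """Read an ASCII (P2) portable graymap."""
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if tokens[0] != "P2":
        raise GridError(f"not an ASCII PGM (P2) file: magic {tokens[0]!r}")
    w, h, _maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array(tokens[4:4 + w * h], dtype=int)
    return data.reshape(h, w)


def write_pgm(path, array: np.ndarray):
    arr = np.asarray(array, dtype=int)
    h, w = arr.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n{max(1, arr.max())}\n")
        for row in arr:
            fh.write(" ".join(map(str, row)) + "\n")
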