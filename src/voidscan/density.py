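"""Neighbor-averaged local density on the periodic voxel grid.

Density is a statistical property that is meaningless at the scale of a
single 1 Å voxel (most voxels of liquid water hold no atom at all).  Each
cell's density is therefore averaged over a spherical stencil of surrounding
cells: the summed mass of all cells within the stencil divided by the
stencil's total volume.  Edge cells wrap periodically, so cells near the grid
boundary see the contributions of the neighboring periodic images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .pbc_grid import GridSpec, MassGrid

__all__ = [
    "G_PER_L_PER_DA_PER_A3",
    "DetectionConfig",
    "DensityGrid",
    "neighborhood_offsets",
    "neighbor_density",
    "density_oracle",
]

#: Unit conversion: 1 Da/Å^3 = 1660.539 g/L (1 Da = 1/N_A grams,
#: 1 Å^3 = 1e-27 L).  Liquid water at 1000 g/L is ~0.602 Da/Å^3.
G_PER_L_PER_DA_PER_A3 = 1660.539


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the void-detection pipeline.

    resolution : float
        Grid resolution in Å (default 1).
    neighbor_cells : int
        Stencil radius in cells (default 4; at 1 Å resolution this averages
        over neighbors up to 4 Å away in all directions).
    density_cutoff : float
        Density in g/L below which a cell counts as void (default 0.25, i.e.
        1/4000 of liquid water — effectively "no mass anywhere nearby").
    min_bubble_volume : float
        Minimum connected void volume in nm^3 for a bubble to be reported
        (default 0.1; a component must strictly exceed this).
    connectivity : int
        6 (faces) or 26 (faces+edges+corners) voxel adjacency (default 26).
    periodic_labeling : bool
        Whether component adjacency wraps across the box boundaries
        (default True), merging bubble fragments split by wrapping.
    """

    resolution: float = 1.0
    neighbor_cells: int = 4
    density_cutoff: float = 0.25
    min_bubble_volume: float = 0.1
    connectivity: int = 26
    periodic_labeling: bool = True

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.neighbor_cells < 0:
            raise ValueError("neighbor_cells must be >= 0")
        if self.density_cutoff <= 0:
            raise ValueError("density_cutoff must be > 0")
        if self.min_bubble_volume <= 0:
            raise ValueError("min_bubble_volume must be > 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class DensityGrid:
    """Neighbor-averaged local density in g/L per voxel."""

    spec: GridSpec
    density: np.ndarray
    neighbor_cells: int

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != self.spec.shape:
            raise ValueError(
                f"density shape {self.density.shape} != grid {self.spec.shape}"
            )


def neighborhood_offsets(n: int) -> np.ndarray:
    """Integer offsets (i, j, k) with i^2 + j^2 + k^2 <= n^2, center included.

    This is the discrete spherical stencil; membership is measured in cell
    offsets, not Å, so the stencil's physical radius is n cells times the
    cell length (equal to n Å at the default 1 Å resolution).
    """
    if n < 0:
        raise ValueError("stencil radius must be >= 0")
    r = np.arange(-n, n + 1)
    i, j, k = np.meshgrid(r, r, r, indexing="ij")
    inside = i * i + j * j + k * k <= n * n
    return np.stack([i[inside], j[inside], k[inside]], axis=1)


def _stencil_kernel(n: int) -> np.ndarray:
    r = np.arange(-n, n + 1)
    i, j, k = np.meshgrid(r, r, r, indexing="ij")
    return (i * i + j * j + k * k <= n * n).astype(float)


def neighbor_density(grid: MassGrid, n: int) -> DensityGrid:
    """Spherically neighbor-averaged density in g/L with periodic edges.

    For each cell, the masses of all cells within the stencil (indices taken
    modulo the grid shape) are summed and divided by the stencil volume
    (stencil size x one cell volume; under periodicity every stencil cell
    exists, so no partial-neighborhood correction is needed).
    """
    kernel = _stencil_kernel(n)
    summed = ndimage.convolve(grid.cell_mass, kernel, mode="wrap")
    volume = kernel.sum() * grid.spec.cell_volume  # Å^3
    density = summed / volume * G_PER_L_PER_DA_PER_A3
    return DensityGrid(spec=grid.spec, density=density, neighbor_cells=n)


def density_oracle(grid: MassGrid, n: int) -> DensityGrid:
    """Reference implementation of :func:`neighbor_density` for testing.

    Direct per-cell loops with explicit modular indexing; identical contract,
    practical only for small grids (<= ~64^3).  Kept independent of the
    convolution path on purpose.
    """
    offsets = neighborhood_offsets(n)
    dx, dy, dz = offsets[:, 0], offsets[:, 1], offsets[:, 2]
    nx, ny, nz = grid.spec.counts
    mass = grid.cell_mass
    out = np.zeros_like(mass)
    volume = len(offsets) * grid.spec.cell_volume
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                s = mass[(x + dx) % nx, (y + dy) % ny, (z + dz) % nz].sum()
                out[x, y, z] = s / volume * G_PER_L_PER_DA_PER_A3
    return DensityGrid(spec=grid.spec, density=out, neighbor_cells=n)
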