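"""Independent brute-force reference implementations used only by tests and
the acceptance script.  Each oracle is built from first principles (explicit
enumeration, union-find over a modular adjacency list, roll-based erosion)
and shares no code path with the implementation it checks."""

from __future__ import annotations

import numpy as np


def offsets_bruteforce(n: int) -> set[tuple[int, int, int]]:
    """All integer triples with i^2 + j^2 + k^2 <= n^2, by enumeration."""
    out = set()
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                if i * i + j * j + k * k <= n * n:
                    out.add((i, j, k))
    return out


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                if (i, j, k) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(i) + abs(j) + abs(k) != 1:
                    continue
                offs.append((i, j, k))
    return offs


def label_oracle(
    mask: np.ndarray, connectivity: int, periodic: bool
) -> tuple[np.ndarray, int]:
    """Connected components by plain union-find over an explicit adjacency
    list with modular (or clipped) index arithmetic; labels renumbered in
    first-encounter raster-scan order to match the library contract."""
    mask = np.asarray(mask, dtype=bool)
    nx, ny, nz = mask.shape
    parent: dict[tuple[int, int, int], tuple[int, int, int]] = {}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    voxels = [tuple(v) for v in np.argwhere(mask)]
    for v in voxels:
        parent[v] = v
    offs = _neighbor_offsets(connectivity)
    for (x, y, z) in voxels:
        for (i, j, k) in offs:
            if periodic:
                w = ((x + i) % nx, (y + j) % ny, (z + k) % nz)
            else:
                w = (x + i, y + j, z + k)
                if not (0 <= w[0] < nx and 0 <= w[1] < ny and 0 <= w[2] < nz):
                    continue
            if w in parent:
                union((x, y, z), w)
    labels = np.zeros(mask.shape, dtype=np.int32)
    next_label = 0
    root_label: dict[tuple[int, int, int], int] = {}
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                r = find((x, y, z))
                if r not in root_label:
                    next_label += 1
                    root_label[r] = next_label
                labels[x, y, z] = root_label[r]
    return labels, next_label


def erosion_void_oracle(cell_mass: np.ndarray, n: int) -> np.ndarray:
    """Expected void mask for point-particle systems with a far-sub-density
    cutoff: exactly the cells whose full spherical stencil holds zero mass
    (a periodic morphological erosion of the empty-cell mask)."""
    occupied = np.asarray(cell_mass) > 0
    any_mass = np.zeros_like(occupied)
    for (i, j, k) in offsets_bruteforce(n):
        any_mass |= np.roll(occupied, shift=(-i, -j, -k), axis=(0, 1, 2))
    return ~any_mass


def surface_voxel_count(mask: np.ndarray) -> int:
    """Void voxels with at least one non-void 6-neighbor (periodic)."""
    mask = np.asarray(mask, dtype=bool)
    surface = np.zeros_like(mask)
    for axis in range(3):
        for shift in (-1, 1):
            surface |= mask & ~np.roll(mask, shift, axis=axis)
    return int(surface.sum())
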