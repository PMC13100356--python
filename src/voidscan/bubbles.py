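"""Void classification, periodic connected-component labeling, and bubble
statistics.

A *void* is a voxel whose neighbor-averaged density falls below the cutoff; a
*bubble* is a connected set of void voxels whose volume exceeds the minimum.
Connectivity may wrap across the periodic boundaries, so the fragments of one
physical bubble that wrapping has scattered into different corners of the box
are labeled as a single component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .trajectory_io import AtomFrame
from .pbc_grid import GridSpec, MassGrid, make_grid, voxelize, wrap_to_brick
from .density import DensityGrid, DetectionConfig, neighbor_density

__all__ = [
    "VoidMask",
    "Bubble",
    "FrameReport",
    "classify_voids",
    "label_components",
    "summarize_bubbles",
    "analyze_frame",
    "analyze_trajectory",
    "match_bubbles_across_frames",
]

logger = logging.getLogger(__name__)

A3_PER_NM3 = 1000.0


@dataclass
class VoidMask:
    """Boolean void field on the grid (True = sub-cutoff density)."""

    spec: GridSpec
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.spec.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid {self.spec.shape}"
            )


@dataclass(frozen=True)
class Bubble:
    """One labeled connected void with size and shape statistics.

    volume is in nm^3; centroid (Å) is the periodic circular mean of the
    member voxel centers, so a bubble straddling the box boundary still gets
    an interior centroid; radius_of_gyration (Å) and principal_extents (Å,
    sorted ascending) come from the covariance of the periodically unwrapped
    voxel centers, with each extent reported as the edge length of the
    uniform block with the same variance (2 * sqrt(3 * eigenvalue)).
    """

    label: int
    voxel_count: int
    volume: float
    centroid: tuple[float, float, float]
    radius_of_gyration: float
    principal_extents: tuple[float, float, float]


@dataclass
class FrameReport:
    """Detection result for one frame.

    bubbles are sorted by volume descending; total_void_volume (nm^3) is the
    sum of the reported (post-filter) bubble volumes.  When the frame was
    analyzed with ``keep_fields=True`` the labeled void field and density
    grid are retained for tracking and volumetric output.
    """

    frame_index: int
    bubble_present: bool
    bubbles: list[Bubble]
    total_void_volume: float
    config: DetectionConfig
    spec: Optional[GridSpec] = None
    labels: Optional[np.ndarray] = field(default=None, repr=False)
    density: Optional[DensityGrid] = field(default=None, repr=False)

    @property
    def n_bubbles(self) -> int:
        return len(self.bubbles)


def classify_voids(density: DensityGrid, cutoff: float) -> VoidMask:
    """Mark every cell with density strictly below ``cutoff`` (g/L) as void."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return VoidMask(spec=density.spec, mask=density.density < cutoff)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _stitch_axis(labels: np.ndarray, axis: int, connectivity: int,
                 uf: _UnionFind) -> None:
    """Union labels adjacent across the periodic boundary of one axis."""
    lo = np.take(labels, 0, axis=axis)
    hi = np.take(labels, -1, axis=axis)
    if connectivity == 6:
        offsets = [(0, 0)]
    else:
        offsets = [(dy, dz) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    for dy, dz in offsets:
        shifted = np.roll(np.roll(hi, dy, axis=0), dz, axis=1)
        both = (lo > 0) & (shifted > 0)
        if not both.any():
            continue
        pairs = np.unique(
            np.stack([lo[both], shifted[both]], axis=1), axis=0
        )
        for a, b in pairs:
            uf.union(int(a), int(b))


def label_components(
    mask: VoidMask, connectivity: int = 26, periodic: bool = True
) -> tuple[np.ndarray, int]:
    """Partition void voxels into maximal connected components.

    Returns ``(labels, count)`` where labels is an integer field (0 =
    non-void) with component labels 1..count assigned in first-encounter
    scan order.  With ``periodic`` on, adjacency wraps across all three axis
    boundaries, so fragments of one bubble split by wrapping share a label.
    """
    structure = _structure(connectivity)
    labels, n = ndimage.label(mask.mask, structure=structure)
    if n == 0:
        return labels, 0
    if periodic:
        uf = _UnionFind(n + 1)
        for axis in range(3):
            _stitch_axis(labels, axis, connectivity, uf)
        root = np.array([uf.find(i) for i in range(n + 1)])
        labels = root[labels]
    # renumber 1..K in first-encounter (C-order raster scan) order
    flat = labels.ravel()
    present, first = np.unique(flat, return_index=True)
    keep = present > 0
    order = np.argsort(first[keep])
    new_of = np.zeros(int(present.max()) + 1, dtype=labels.dtype)
    new_of[present[keep][order]] = np.arange(1, keep.sum() + 1)
    return new_of[labels], int(keep.sum())


def _component_stats(
    coords: np.ndarray, spec: GridSpec
) -> tuple[tuple[float, float, float], float, tuple[float, float, float]]:
    """Periodic-aware centroid, radius of gyration, principal extents.

    coords are voxel-center positions in Å of one component's members.
    Centroid per axis is the circular mean (cells mapped to angles on the
    periodic circle, averaged, mapped back); moments are taken over the
    coordinates unwrapped to the nearest periodic image of that centroid.
    """
    lengths = np.asarray(spec.box_lengths)
    theta = coords / lengths * (2 * np.pi)
    mean_sin = np.sin(theta).mean(axis=0)
    mean_cos = np.cos(theta).mean(axis=0)
    centroid = np.arctan2(mean_sin, mean_cos) / (2 * np.pi) * lengths
    centroid = np.mod(centroid, lengths)
    # unwrap members to the image nearest the centroid (valid while the
    # bubble's extent stays below half the box on each axis)
    delta = coords - centroid
    delta -= np.round(delta / lengths) * lengths
    delta -= delta.mean(axis=0)
    cov = delta.T @ delta / len(delta)
    rg = float(np.sqrt(np.trace(cov)))
    eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    extents = tuple(float(2.0 * np.sqrt(3.0 * ev)) for ev in np.sort(eigvals))
    return tuple(float(v) for v in centroid), rg, extents


def summarize_bubbles(
    labels: np.ndarray, spec: GridSpec, min_volume: float
) -> list[Bubble]:
    """Turn labeled components into Bubble records, dropping small ones.

    A component is reported only if its volume strictly exceeds
    ``min_volume`` (nm^3); a component exactly at the threshold is
    suppressed.  Survivors are sorted by volume descending (ties by label).
    """
    labels = np.asarray(labels)
    if labels.max(initial=0) == 0:
        return []
    counts = np.bincount(labels.ravel())
    cell_vol = spec.cell_volume  # Å^3
    threshold_a3 = min_volume * A3_PER_NM3
    h = np.asarray(spec.cell_lengths)
    bubbles: list[Bubble] = []
    for lab in range(1, len(counts)):
        n_vox = int(counts[lab])
        if n_vox == 0:
            continue
        vol_a3 = n_vox * cell_vol
        if vol_a3 <= threshold_a3 or np.isclose(vol_a3, threshold_a3, rtol=1e-9):
            continue
        idx = np.argwhere(labels == lab)
        coords = (idx + 0.5) * h
        centroid, rg, extents = _component_stats(coords, spec)
        bubbles.append(
            Bubble(
                label=lab,
                voxel_count=n_vox,
                volume=vol_a3 / A3_PER_NM3,
                centroid=centroid,
                radius_of_gyration=rg,
                principal_extents=extents,
            )
        )
    bubbles.sort(key=lambda b: (-b.volume, b.label))
    return bubbles


def analyze_frame(
    frame: AtomFrame,
    config: DetectionConfig = DetectionConfig(),
    keep_fields: bool = False,
) -> FrameReport:
    """Run the full detection pipeline on one frame.

    wrap -> grid -> voxel masses -> neighbor-averaged density -> void
    classification -> periodic component labeling -> bubble statistics.
    Deterministic for fixed input.  With ``keep_fields`` the labeled void
    field and the density grid are attached to the report (needed for
    volumetric output and cross-frame tracking).
    """
    wrapped = wrap_to_brick(frame)
    spec = make_grid(frame.box, config.resolution)
    mass = voxelize(wrapped, spec)
    dens = neighbor_density(mass, config.neighbor_cells)
    mask = classify_voids(dens, config.density_cutoff)
    labels, _ = label_components(
        mask, connectivity=config.connectivity, periodic=config.periodic_labeling
    )
    bubbles = summarize_bubbles(labels, spec, config.min_bubble_volume)
    return FrameReport(
        frame_index=frame.frame_index,
        bubble_present=bool(bubbles),
        bubbles=bubbles,
        total_void_volume=float(sum(b.volume for b in bubbles)),
        config=config,
        spec=spec,
        labels=labels if keep_fields else None,
        density=dens if keep_fields else None,
    )


def analyze_trajectory(
    frames: Iterable[AtomFrame],
    config: DetectionConfig = DetectionConfig(),
    keep_fields: bool = False,
) -> list[FrameReport]:
    """Analyze frames independently, in input order, with constant memory
    per frame (the input may be a lazy iterator)."""
    reports: list[FrameReport] = []
    for frame in frames:
        try:
            reports.append(analyze_frame(frame, config, keep_fields=keep_fields))
        except Exception as exc:
            raise RuntimeError(
                f"analysis failed at frame {frame.frame_index}: {exc}"
            ) from exc
    return reports


def match_bubbles_across_frames(
    reports: Sequence[FrameReport],
) -> list[list[tuple[int, int]]]:
    """Link bubbles between consecutive frames by voxel overlap.

    Returns tracks, each a list of ``(frame_index, label)`` pairs.  Matching
    is greedy on maximum voxel overlap (ties: larger overlap wins, equal
    overlaps broken by lower label pair); unmatched bubbles start or end
    tracks.  Purely a reporting layer — detection results are untouched.
    Requires reports produced with ``keep_fields=True``; consecutive frames
    with differing grid shapes are not linked (a notice is logged).
    """
    tracks: list[list[tuple[int, int]]] = []
    open_tracks: dict[int, list[tuple[int, int]]] = {}  # label in prev frame
    prev: Optional[FrameReport] = None
    for rep in reports:
        if rep.labels is None:
            raise ValueError(
                "match_bubbles_across_frames needs reports with keep_fields=True"
            )
        cur_labels = {b.label for b in rep.bubbles}
        assignment: dict[int, int] = {}  # current label -> previous label
        if prev is not None and cur_labels and open_tracks:
            if prev.labels.shape != rep.labels.shape:
                logger.info(
                    "grid shape changed between frames %d and %d; "
                    "tracking not linked across this boundary",
                    prev.frame_index,
                    rep.frame_index,
                )
            else:
                assignment = _greedy_overlap_match(
                    prev.labels, rep.labels, set(open_tracks), cur_labels
                )
        new_open: dict[int, list[tuple[int, int]]] = {}
        for lab in sorted(cur_labels):
            if lab in assignment:
                track = open_tracks[assignment[lab]]
            else:
                track = []
                tracks.append(track)
            track.append((rep.frame_index, lab))
            new_open[lab] = track
        open_tracks = new_open
        prev = rep
    return tracks


def _greedy_overlap_match(
    prev_labels: np.ndarray,
    cur_labels: np.ndarray,
    prev_set: set[int],
    cur_set: set[int],
) -> dict[int, int]:
    p = prev_labels.ravel()
    c = cur_labels.ravel()
    both = (p > 0) & (c > 0)
    if not both.any():
        return {}
    pmax = int(p.max()) + 1
    cmax = int(c.max()) + 1
    joint = np.bincount(p[both] * cmax + c[both], minlength=pmax * cmax)
    pairs = []
    for flat in np.flatnonzero(joint):
        pl, cl = divmod(int(flat), cmax)
        if pl in prev_set and cl in cur_set:
            pairs.append((int(joint[flat]), pl, cl))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_prev: set[int] = set()
    assignment: dict[int, int] = {}
    for overlap, pl, cl in pairs:
        if pl in used_prev or cl in assignment:
            continue
        assignment[cl] = pl
        used_prev.add(pl)
    return assignment
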