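"""OpenDX volumetric output and machine-readable per-frame reports."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pbc_grid import GridSpec
from .bubbles import FrameReport

__all__ = [
    "DXField",
    "write_dx",
    "density_field",
    "void_mask_field",
    "label_field",
    "write_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class DXField:
    """A scalar field on the grid ready for OpenDX output.

    The origin is the center of voxel (0,0,0) — values are cell-averaged
    quantities, so visualization overlays align with voxel centers.
    """

    spec: GridSpec
    origin: tuple[float, float, float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid {self.spec.shape}"
            )


def density_field(report: FrameReport) -> DXField:
    """Neighbor-averaged density (g/L) of a ``keep_fields=True`` report."""
    if report.density is None:
        raise ValueError("report lacks density; analyze with keep_fields=True")
    return _field(report.spec, report.density.density)


def void_mask_field(report: FrameReport) -> DXField:
    """0/1 field marking voxels of reported (post-filter) bubbles."""
    if report.labels is None:
        raise ValueError("report lacks labels; analyze with keep_fields=True")
    kept = np.isin(report.labels, [b.label for b in report.bubbles])
    return _field(report.spec, kept.astype(float))


def label_field(report: FrameReport) -> DXField:
    """Integer bubble labels (0 = solvent / filtered) as a scalar field."""
    if report.labels is None:
        raise ValueError("report lacks labels; analyze with keep_fields=True")
    return _field(report.spec, report.labels.astype(float))


def _field(spec: GridSpec, values: np.ndarray) -> DXField:
    hx, hy, hz = spec.cell_lengths
    return DXField(spec=spec, origin=(hx / 2, hy / 2, hz / 2), values=values)


def write_dx(field: DXField, path) -> Path:
    """Write an OpenDX scalar field readable by VMD/PyMOL/gridData.

    Layout: gridpositions counts, origin, three axis-aligned delta lines,
    gridconnections, then the values three per line with the z index varying
    fastest (C-order raveling of the [x, y, z] array).
    """
    path = Path(path)
    nx, ny, nz = field.spec.counts
    hx, hy, hz = field.spec.cell_lengths
    ox, oy, oz = field.origin
    flat = field.values.ravel(order="C")
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6g} {oy:.6g} {oz:.6g}",
        f"delta {hx:.9g} 0 0",
        f"delta 0 {hy:.9g} 0",
        f"delta 0 0 {hz:.9g}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {flat.size} data follows",
    ]
    for i in range(0, flat.size, 3):
        chunk = flat[i : i + 3]
        lines.append(" ".join(f"{v:.9g}" for v in chunk))
    lines.append('object "density" class field')
    lines.append("")
    try:
        path.write_text("\n".join(lines))
    except OSError as exc:
        raise OSError(f"cannot write DX file {path}: {exc}") from exc
    return path


def _bubble_dict(b) -> dict:
    return {
        "label": b.label,
        "voxel_count": b.voxel_count,
        "volume_nm3": b.volume,
        "centroid_A": list(b.centroid),
        "radius_of_gyration_A": b.radius_of_gyration,
        "principal_extents_A": list(b.principal_extents),
    }


def _config_dict(cfg) -> dict:
    return {
        "resolution_A": cfg.resolution,
        "neighbor_cells": cfg.neighbor_cells,
        "density_cutoff_g_per_L": cfg.density_cutoff,
        "min_bubble_volume_nm3": cfg.min_bubble_volume,
        "connectivity": cfg.connectivity,
        "periodic_labeling": cfg.periodic_labeling,
    }


def frame_record(report: FrameReport) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "frame": report.frame_index,
        "bubble_present": report.bubble_present,
        "n_bubbles": report.n_bubbles,
        "volumes_nm3": [b.volume for b in report.bubbles],
        "total_void_volume_nm3": report.total_void_volume,
        "bubbles": [_bubble_dict(b) for b in report.bubbles],
        "config": _config_dict(report.config),
    }


_CSV_COLUMNS = [
    "schema_version", "frame", "bubble_present", "n_bubbles", "label",
    "voxel_count", "volume_nm3", "centroid_x_A", "centroid_y_A",
    "centroid_z_A", "radius_of_gyration_A", "extent_1_A", "extent_2_A",
    "extent_3_A", "total_void_volume_nm3",
]


def write_report(
    reports: Sequence[FrameReport], path, format: str = "json"
) -> Path:
    """Serialize per-frame results as JSON (one object per frame) or CSV
    (one row per bubble per frame; bubble-free frames emit a single row
    with empty bubble columns)."""
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps([frame_record(r) for r in reports], indent=1) + "\n"
        )
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for r in reports:
                common = [REPORT_SCHEMA_VERSION, r.frame_index,
                          r.bubble_present, r.n_bubbles]
                if not r.bubbles:
                    writer.writerow(common + [""] * 10 + [r.total_void_volume])
                for b in r.bubbles:
                    writer.writerow(
                        common
                        + [b.label, b.voxel_count, b.volume]
                        + list(b.centroid)
                        + [b.radius_of_gyration]
                        + list(b.principal_extents)
                        + [r.total_void_volume]
                    )
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path
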