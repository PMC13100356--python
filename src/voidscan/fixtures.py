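"""Synthetic test systems: solvent lattices, carved voids, triclinic cells,
membrane-like density profiles, and shrinking-bubble trajectories.

Real explicit-solvent boxes are emulated by jitter-free simple-cubic
lattices of single mass points (one 18.015 Da bead per water).  The
detection pipeline consumes nothing but mass points, so point beads keep
every expected value exactly computable: with the default 0.25 g/L cutoff a
voxel is void precisely when its whole stencil contains no bead, which makes
the morphological-erosion oracle exact on these fixtures.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .trajectory_io import AtomFrame, BoxVectors
from .density import G_PER_L_PER_DA_PER_A3
from .pbc_grid import wrap_to_brick

__all__ = [
    "WATER_MASS",
    "lattice_spacing",
    "water_lattice",
    "carve_sphere",
    "carve_slab",
    "triclinic_solvent",
    "membrane_like",
    "shrinking_bubble_trajectory",
    "write_structure",
    "write_frames",
]

#: Mass of one water bead in Da.
WATER_MASS = 18.015


def lattice_spacing(target_density: float, particle_mass: float = WATER_MASS) -> float:
    """Cubic lattice spacing (Å) giving ``target_density`` in g/L.

    s^3 = m * 1660.539 / rho; 1000 g/L of water beads gives s ≈ 3.104 Å.
    """
    if target_density <= 0:
        raise ValueError("target_density must be > 0")
    return float((particle_mass * G_PER_L_PER_DA_PER_A3 / target_density) ** (1.0 / 3.0))


def _axis_counts(
    lengths: Sequence[float], spacing: float, n_ideal: Optional[float] = None
) -> tuple[int, int, int]:
    """Per-axis point counts whose product best matches the ideal number.

    Independent per-axis rounding of L/s can miss the target density by
    ~3x the per-axis rounding error; searching count combinations near
    L/s (allowing up to 20% per-axis spacing distortion) for the product
    closest to the ideal count keeps the mean density within ~2% for boxes
    of 30 Å and up.  ``n_ideal`` overrides the product target when the cell
    volume differs from the product of the edge lengths (triclinic cells).
    """
    ideal = [li / spacing for li in lengths]
    if n_ideal is None:
        n_ideal = float(np.prod(ideal))
    axis_candidates = []
    for x in ideal:
        cands = {max(1, int(np.floor(x)) + d) for d in range(-3, 4)}
        ok = sorted(c for c in cands if abs(x / c - 1.0) <= 0.2) or [
            max(1, int(np.floor(x + 0.5)))
        ]
        axis_candidates.append(ok)
    best = None
    for combo in itertools.product(*axis_candidates):
        err = abs(float(np.prod(combo)) - n_ideal)
        distortion = sum(abs(x / c - 1.0) for x, c in zip(ideal, combo))
        if best is None or (err, distortion) < best[:2]:
            best = (err, distortion, combo)
    return best[2]


def water_lattice(
    box_lengths: Sequence[float],
    target_density: float = 1000.0,
    particle_mass: float = WATER_MASS,
) -> AtomFrame:
    """Uniform solvent: a simple-cubic lattice of mass points filling the box.

    Bead positions are cell centers of an ``nx x ny x nz`` lattice chosen so
    the achieved mean density is within ~2% of ``target_density`` (g/L).
    """
    lengths = tuple(float(v) for v in box_lengths)
    s = lattice_spacing(target_density, particle_mass)
    if min(lengths) < s:
        raise ValueError(
            f"box {lengths} smaller than one lattice spacing ({s:.3f} Å) "
            f"at {target_density} g/L"
        )
    counts = _axis_counts(lengths, s)
    axes = [
        (np.arange(ni) + 0.5) * (li / ni) for ni, li in zip(counts, lengths)
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    box = BoxVectors(
        (lengths[0], 0.0, 0.0), (0.0, lengths[1], 0.0), (0.0, 0.0, lengths[2])
    )
    return AtomFrame(
        coordinates=coords,
        masses=np.full(len(coords), particle_mass),
        box=box,
    )


def _min_image_dist(coords: np.ndarray, center: np.ndarray, box: BoxVectors) -> np.ndarray:
    """Minimum-image distances to ``center`` under the full triclinic lattice."""
    m = box.matrix
    delta = coords - center[None, :]
    frac = delta @ np.linalg.inv(m)
    frac -= np.round(frac)
    # round-based reduction is minimal for modest shears; scan the 27
    # neighbor images to be exact for any cell this package accepts
    best = np.full(len(delta), np.inf)
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                cart = (frac + np.array([sx, sy, sz])) @ m
                d = np.linalg.norm(cart, axis=1)
                np.minimum(best, d, out=best)
    return best


def carve_sphere(
    frame: AtomFrame, center: Sequence[float], radius: float
) -> AtomFrame:
    """Remove every particle closer than ``radius`` (Å, minimum image) to
    ``center``; a sphere centered near a box corner therefore carves a void
    that straddles the periodic boundaries."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0 or frame.n_atoms == 0:
        return frame
    dist = _min_image_dist(frame.coordinates, np.asarray(center, float), frame.box)
    keep = dist >= radius
    return AtomFrame(
        coordinates=frame.coordinates[keep],
        masses=frame.masses[keep],
        box=frame.box,
        frame_index=frame.frame_index,
    )


def carve_slab(frame: AtomFrame, axis: int, lo: float, hi: float) -> AtomFrame:
    """Remove particles whose ``axis`` coordinate lies in [lo, hi)."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    if hi < lo:
        raise ValueError(f"degenerate slab range [{lo}, {hi})")
    coord = frame.coordinates[:, axis]
    keep = ~((coord >= lo) & (coord < hi))
    return AtomFrame(
        coordinates=frame.coordinates[keep],
        masses=frame.masses[keep],
        box=frame.box,
        frame_index=frame.frame_index,
    )


def triclinic_solvent(
    box: BoxVectors,
    target_density: float = 1000.0,
    particle_mass: float = WATER_MASS,
) -> AtomFrame:
    """Fill a (possibly triclinic) cell with a lattice built in fractional
    coordinates, then wrap into the rectangular brick."""
    s = lattice_spacing(target_density, particle_mass)
    m = box.matrix
    edge_lengths = np.linalg.norm(m, axis=1)
    if min(edge_lengths) < s:
        raise ValueError("cell smaller than one lattice spacing")
    counts = _axis_counts(tuple(edge_lengths), s, n_ideal=box.volume / s**3)
    axes = [(np.arange(ni) + 0.5) / ni for ni in counts]
    fx, fy, fz = np.meshgrid(*axes, indexing="ij")
    frac = np.stack([fx.ravel(), fy.ravel(), fz.ravel()], axis=1)
    coords = frac @ m
    frame = AtomFrame(
        coordinates=coords,
        masses=np.full(len(coords), particle_mass),
        box=box,
    )
    return wrap_to_brick(frame)


def membrane_like(
    box_lengths: Sequence[float],
    mid_density: float = 700.0,
    mid_fraction: float = 1.0 / 3.0,
    bulk_density: float = 1000.0,
) -> AtomFrame:
    """Bilayer-like z-profile: bulk-density solvent with a reduced-density
    (but far-above-cutoff) mid-plane slab.

    Exercises the false-positive case: a lipid-tail region is less dense
    than water but is not a void.  ``mid_density`` must stay at or above
    600 g/L so the fixture remains a guaranteed true negative by
    construction (2400x the default cutoff).
    """
    if not 0 < mid_fraction < 1:
        raise ValueError("mid_fraction must be in (0, 1)")
    if mid_density < 600.0:
        raise ValueError(
            "mid_density below 600 g/L would not be a guaranteed true "
            "negative; this fixture models a dense-but-reduced bilayer core"
        )
    lengths = tuple(float(v) for v in box_lengths)
    lz = lengths[2]
    z_lo = lz * (0.5 - mid_fraction / 2.0)
    z_hi = lz * (0.5 + mid_fraction / 2.0)
    # three independent sub-lattices, so each slab hits its own target
    # density regardless of where the slab boundaries cut a shared lattice
    pieces = [
        (water_lattice((lengths[0], lengths[1], z_lo), bulk_density), 0.0),
        (water_lattice((lengths[0], lengths[1], z_hi - z_lo), mid_density), z_lo),
        (water_lattice((lengths[0], lengths[1], lz - z_hi), bulk_density), z_hi),
    ]
    coords = np.vstack([
        p.coordinates + np.array([0.0, 0.0, shift]) for p, shift in pieces
    ])
    masses = np.concatenate([p.masses for p, _ in pieces])
    box = BoxVectors(
        (lengths[0], 0.0, 0.0), (0.0, lengths[1], 0.0), (0.0, 0.0, lz)
    )
    return AtomFrame(coordinates=coords, masses=masses, box=box)


def shrinking_bubble_trajectory(
    n_frames: int,
    initial_radius: float,
    box_lengths: Sequence[float],
    target_density: float = 1000.0,
    center: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> list[AtomFrame]:
    """Frames of a bubble shrinking linearly to nothing.

    Frame t is carved with radius ``r_t = initial_radius * (1 - t/(n-1))``;
    the final frame is the intact lattice.  The atom count is held constant
    (as any trajectory format requires) by relocating the beads from inside
    the sphere to seeded-random positions outside it — mimicking solvent
    compressed out of a cavity at constant volume.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    lengths = tuple(float(v) for v in box_lengths)
    base = water_lattice(lengths, target_density)
    if center is None:
        center = np.asarray(lengths) / 2.0
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    frames: list[AtomFrame] = []
    for t in range(n_frames):
        r = 0.0 if n_frames == 1 else initial_radius * (1.0 - t / (n_frames - 1))
        coords = base.coordinates.copy()
        if r > 0:
            dist = _min_image_dist(coords, center, base.box)
            inside = dist < r
            n_in = int(inside.sum())
            if n_in:
                coords[inside] = _sample_outside(
                    rng, n_in, base.box, center, r
                )
        frames.append(
            AtomFrame(
                coordinates=coords,
                masses=base.masses.copy(),
                box=base.box,
                frame_index=t,
            )
        )
    return frames


def _sample_outside(rng, n, box: BoxVectors, center, radius) -> np.ndarray:
    """Uniform points in the brick at minimum-image distance >= radius."""
    out = np.empty((n, 3))
    lengths = np.asarray(box.brick_lengths)
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, 1.0, size=(max(2 * (n - filled), 64), 3)) * lengths
        ok = _min_image_dist(cand, np.asarray(center, float), box) >= radius
        take = cand[ok][: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


# ---------------------------------------------------------------------------
# file output (PDB / GRO / multi-model PDB trajectories) via MDAnalysis


def _as_universe(frame: AtomFrame, element: str):
    import MDAnalysis as mda

    n = frame.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", [element + "W"] * n)
    u.add_TopologyAttr("elements", [element] * n)
    u.add_TopologyAttr("resnames", ["SOL"] * n)
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.add_TopologyAttr("masses", frame.masses)
    u.atoms.positions = frame.coordinates
    u.dimensions = frame.box.to_lengths_angles()
    return u


def write_structure(frame: AtomFrame, path, element: str = "O") -> Path:
    """Write one frame as PDB (with CRYST1) or GRO, chosen by extension.

    PDB and GRO store no masses; a re-read frame gets masses inferred from
    the element written here, so exact mass round-trips require the bead
    mass to equal that element's standard weight.
    """
    import warnings

    path = Path(path)
    u = _as_universe(frame, element)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def write_frames(
    frames: Sequence[AtomFrame], directory, basename: str = "system",
    element: str = "O",
) -> tuple[Path, Path]:
    """Write a structure PDB plus a multi-model PDB trajectory.

    Returns ``(structure_path, trajectory_path)`` suitable for
    :func:`voidscan.trajectory_io.iter_frames` and the command-line tool.
    All frames must share an atom count.
    """
    import warnings

    import MDAnalysis as mda

    if not frames:
        raise ValueError("no frames to write")
    counts = {f.n_atoms for f in frames}
    if len(counts) != 1:
        raise ValueError(f"frames have differing atom counts: {sorted(counts)}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    structure = directory / f"{basename}.pdb"
    trajectory = directory / f"{basename}_traj.pdb"
    write_structure(frames[0], structure, element=element)
    u = _as_universe(frames[0], element)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(trajectory), multiframe=True,
                        n_atoms=frames[0].n_atoms) as w:
            for f in frames:
                u.atoms.positions = f.coordinates
                u.dimensions = f.box.to_lengths_angles()
                w.write(u.atoms)
    _insert_per_model_cryst1(trajectory, frames)
    return structure, trajectory


def _insert_per_model_cryst1(path: Path, frames: Sequence[AtomFrame]) -> None:
    """Put each frame's CRYST1 inside its MODEL block.

    Multi-model PDB readers take per-frame box vectors from a CRYST1 record
    within the MODEL (a header CRYST1 applies to none of them), and
    constant-pressure boxes genuinely change frame to frame.
    """
    crysts = []
    for f in frames:
        la = f.box.to_lengths_angles()
        crysts.append(
            f"CRYST1{la[0]:9.3f}{la[1]:9.3f}{la[2]:9.3f}"
            f"{la[3]:7.2f}{la[4]:7.2f}{la[5]:7.2f} P 1           1"
        )
    out, model = [], 0
    for line in path.read_text().splitlines():
        out.append(line)
        if line.startswith("MODEL"):
            out.append(crysts[model])
            model += 1
    path.write_text("\n".join(out) + "\n")
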