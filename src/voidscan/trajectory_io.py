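"""Reading molecular structures and trajectories into mass-point frames.

Structures (PDB, GRO) and trajectories (XTC, TRR, DCD, multi-model PDB) are
read through MDAnalysis; every frame is converted to an :class:`AtomFrame`
holding coordinates in Å, per-atom masses in Da, and the periodic box in
lower-triangular lattice-vector form.  All box dialects (CRYST1
lengths+angles, GRO 3- or 9-component box lines) are normalized to that one
convention here, so downstream code never branches on file format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "BoxVectors",
    "AtomFrame",
    "read_structure",
    "iter_frames",
    "infer_masses",
]


@dataclass(frozen=True)
class BoxVectors:
    """Periodic cell as three lattice vectors in lower-triangular form.

    ``a = (ax, 0, 0)``, ``b = (bx, by, 0)``, ``c = (cx, cy, cz)``, all in Å.
    Any parallelepiped cell can be rotated into this convention; an
    orthorhombic box has ``bx = cx = cy = 0``.  The diagonal ``(ax, by, cz)``
    gives the edge lengths of the rectangular brick that tiles space under
    lattice translations.
    """

    a: tuple[float, float, float]
    b: tuple[float, float, float]
    c: tuple[float, float, float]

    def __post_init__(self) -> None:
        ax, ay, az = self.a
        bx, by, bz = self.b
        cx, cy, cz = self.c
        if not (ay == 0.0 and az == 0.0 and bz == 0.0):
            raise ValueError(
                "box vectors must be lower-triangular: a=(ax,0,0), b=(bx,by,0)"
            )
        if not (ax > 0 and by > 0 and cz > 0):
            raise ValueError(
                f"degenerate box: diagonal ({ax}, {by}, {cz}) must be positive"
            )

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with lattice vectors as rows."""
        return np.array([self.a, self.b, self.c], dtype=float)

    @property
    def brick_lengths(self) -> tuple[float, float, float]:
        """(Lx, Ly, Lz) = (ax, by, cz), edge lengths of the wrapping brick."""
        return (self.a[0], self.b[1], self.c[2])

    @property
    def volume(self) -> float:
        """Cell volume in Å^3 (product of the diagonal for this convention)."""
        return self.a[0] * self.b[1] * self.c[2]

    @property
    def is_orthorhombic(self) -> bool:
        return self.b[0] == 0.0 and self.c[0] == 0.0 and self.c[1] == 0.0

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "BoxVectors":
        m = np.asarray(m, dtype=float)
        return cls(tuple(m[0]), tuple(m[1]), tuple(m[2]))

    @classmethod
    def from_lengths_angles(cls, dims: Sequence[float]) -> "BoxVectors":
        """Build from MDAnalysis-style [lx, ly, lz, alpha, beta, gamma]."""
        from MDAnalysis.lib import mdamath

        tri = mdamath.triclinic_vectors(np.asarray(dims, dtype=np.float64))
        # triclinic_vectors zeroes tiny off-diagonals; clean residual noise
        tri = np.where(np.abs(tri) < 1e-12, 0.0, tri)
        return cls.from_matrix(tri)

    def to_lengths_angles(self) -> np.ndarray:
        from MDAnalysis.lib import mdamath

        return np.asarray(
            mdamath.triclinic_box(*self.matrix.astype(np.float64)), dtype=float
        )


@dataclass
class AtomFrame:
    """One configuration: N positions (Å), N masses (Da), periodic box."""

    coordinates: np.ndarray
    masses: np.ndarray
    box: BoxVectors
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        if self.coordinates.shape[0] != self.masses.shape[0]:
            raise ValueError(
                f"{self.coordinates.shape[0]} coordinates but "
                f"{self.masses.shape[0]} masses"
            )
        if self.masses.size and not np.all(self.masses > 0):
            bad = np.flatnonzero(~(self.masses > 0))
            raise ValueError(f"non-positive masses at atom indices {bad[:10]}")
        if self.coordinates.size and not np.all(np.isfinite(self.coordinates)):
            bad = np.flatnonzero(~np.isfinite(self.coordinates).all(axis=1))
            raise ValueError(f"non-finite coordinates at atom indices {bad[:10]}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


# Standard atomic weights in Da, from the MDAnalysis element table, with a
# fallback dict so the module degrades gracefully if the table moves again.
def _element_masses() -> dict[str, float]:
    try:
        from MDAnalysis.guesser.tables import masses as mda_masses

        return {k.upper(): float(v) for k, v in mda_masses.items() if v == v}
    except Exception:  # pragma: no cover - table location varies by version
        return {
            "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
            "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
            "CA": 40.078, "FE": 55.845, "ZN": 65.38, "F": 18.998, "BR": 79.904,
            "I": 126.904,
        }


_ELEMENT_MASSES = _element_masses()


def infer_masses(
    atom_names: Sequence[str],
    elements: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Standard atomic weights (Da) from element symbols or atom names.

    The element column, when present and non-blank, always wins.  Otherwise
    the element is guessed as the first alphabetic character of the atom name
    (the PDB convention for biomolecular atom names such as ``CA``, ``OW``,
    ``HW1``).  Coarse-grained bead masses must come from a topology; they are
    never guessed, so an unrecognizable name is a hard error rather than a
    silent wrong mass.
    """
    n = len(atom_names)
    out = np.empty(n, dtype=float)
    unknown: list[str] = []
    for i in range(n):
        sym = ""
        if elements is not None and i < len(elements) and elements[i]:
            sym = str(elements[i]).strip().upper()
        mass = _ELEMENT_MASSES.get(sym) if sym else None
        if mass is None:
            name = str(atom_names[i]).strip()
            first = next((ch for ch in name if ch.isalpha()), "")
            mass = _ELEMENT_MASSES.get(first.upper())
            # two-letter guess (e.g. "CL1" meaning chlorine) is deliberately
            # NOT attempted: "CA" is an alpha-carbon far more often than calcium
        if mass is None or mass <= 0:
            unknown.append(str(atom_names[i]))
            mass = np.nan
        out[i] = mass
    if unknown:
        raise ValueError(
            "cannot infer a mass for atoms "
            f"{sorted(set(unknown))[:20]}; supply elements or topology masses"
        )
    return out


def _universe(structure_path, trajectory_path=None, format_hint=None):
    import MDAnalysis as mda

    kwargs = {}
    if format_hint:
        kwargs["topology_format" if trajectory_path is None else "format"] = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            if format_hint:
                return mda.Universe(str(structure_path), topology_format=format_hint)
            return mda.Universe(str(structure_path))
        return mda.Universe(str(structure_path), str(trajectory_path))


def _frame_masses(u) -> np.ndarray:
    """Masses from the topology where real, else inferred from names/elements."""
    atoms = u.atoms
    masses = None
    if hasattr(atoms, "masses"):
        m = np.asarray(atoms.masses, dtype=float)
        if m.size and np.all(m > 0):
            masses = m
    if masses is None:
        names = list(atoms.names) if hasattr(atoms, "names") else [""] * len(atoms)
        elems = list(atoms.elements) if hasattr(atoms, "elements") else None
        masses = infer_masses(names, elems)
    return masses


def _box_from_ts(ts, path) -> BoxVectors:
    dims = ts.dimensions
    if dims is None or not np.all(np.asarray(dims[:3]) > 0):
        raise ValueError(
            f"no periodic box in {path!s}: a CRYST1 record / box line with "
            "positive volume is required"
        )
    return BoxVectors.from_lengths_angles(dims)


def read_structure(path, format_hint: Optional[str] = None) -> AtomFrame:
    """Read a single-frame structure (PDB or GRO) into an :class:`AtomFrame`.

    Parameters
    ----------
    path : path-like
        Structure file with periodic box information (CRYST1 record for PDB,
        trailing box line for GRO).
    format_hint : str, optional
        Force a reader (``"PDB"``, ``"GRO"``) when the file extension lies.

    Raises
    ------
    ValueError
        If the box is missing or degenerate (zero volume).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    u = _universe(path, format_hint=format_hint)
    box = _box_from_ts(u.trajectory.ts, path)
    return AtomFrame(
        coordinates=u.atoms.positions.astype(float),
        masses=_frame_masses(u),
        box=box,
        frame_index=0,
    )


def iter_frames(
    structure_path,
    trajectory_path=None,
    start: Optional[int] = None,
    stop: Optional[int] = None,
    stride: Optional[int] = None,
) -> Iterator[AtomFrame]:
    """Stream frames as :class:`AtomFrame` objects, one at a time.

    With no trajectory this yields exactly the structure frame.  With a
    trajectory, frames are produced lazily in file order with per-frame box
    vectors (boxes change frame to frame under constant pressure), so
    arbitrarily long trajectories are processed in bounded memory.

    Raises
    ------
    ValueError
        If the trajectory atom count does not match the structure.
    """
    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FileNotFoundError(str(structure_path))
    if trajectory_path is None:
        yield read_structure(structure_path)
        return
    trajectory_path = Path(trajectory_path)
    if not trajectory_path.exists():
        raise FileNotFoundError(str(trajectory_path))
    try:
        u = _universe(structure_path, trajectory_path)
    except Exception as exc:  # MDAnalysis raises its own mismatch errors
        raise ValueError(
            f"cannot combine {structure_path.name} with "
            f"{trajectory_path.name}: {exc}"
        ) from exc
    masses = _frame_masses(u)
    for ts in u.trajectory[slice(start, stop, stride)]:
        box = _box_from_ts(ts, trajectory_path)
        yield AtomFrame(
            coordinates=u.atoms.positions.astype(float),
            masses=masses,
            box=box,
            frame_index=int(ts.frame),
        )
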