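import numpy as np
import pytest

from voidscan import AtomFrame, BoxVectors, GridSpec, MassGrid
from voidscan import fixtures as fx


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def cube30():
    """Orthorhombic 30 Å cube."""
    return BoxVectors((30.0, 0, 0), (0, 30.0, 0), (0, 0, 30.0))


@pytest.fixture
def water30(cube30):
    """Uniform 1000 g/L bead lattice in a 30 Å cube."""
    return fx.water_lattice((30, 30, 30), 1000.0)


def random_frame(rng, n_atoms=1000, lengths=(25.0, 20.0, 15.0)):
    coords = rng.uniform(-30.0, 60.0, size=(n_atoms, 3))
    masses = rng.uniform(1.0, 40.0, size=n_atoms)
    box = BoxVectors(
        (lengths[0], 0, 0), (0, lengths[1], 0), (0, 0, lengths[2])
    )
    return AtomFrame(coordinates=coords, masses=masses, box=box)


def random_mass_grid(rng, shape, fill=0.5, scale=30.0):
    values = rng.uniform(0.0, scale, size=shape)
    values[rng.uniform(size=shape) > fill] = 0.0
    spec = GridSpec(
        counts=tuple(shape),
        cell_lengths=(1.0, 1.0, 1.0),
        box_lengths=tuple(float(s) for s in shape),
    )
    return MassGrid(spec=spec, cell_mass=values)
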