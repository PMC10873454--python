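import numpy as np
import pytest

from xynrin.rin import IType
from xynrin.structio import Atom, Residue, Structure
from xynrin.synthetic import (FixtureSpec, PlantSpec, make_random_structure,
                              make_structure_fixture, random_rotation)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_residue(chain, num, name, atoms):
    """atoms: list of (atom_name, element, (x, y, z))."""
    return Residue(chain, num, "", name,
                   [Atom(n, e, np.asarray(xyz, float)) for n, e, xyz in atoms])


@pytest.fixture
def six_type_fixture():
    """One planted pair of every interaction type plus one decoy each."""
    spec = FixtureSpec(seed=7, planted=[PlantSpec(t, margin=0.3) for t in IType],
                       n_decoys=1, n_filler=2)
    return make_structure_fixture(spec)


@pytest.fixture
def random_structure():
    return make_random_structure(n_residues=50, seed=99, box_size=32.0)


def rigid_transform(rng):
    rot = random_rotation(rng)
    trans = rng.uniform(-50.0, 50.0, size=3)
    return rot, trans
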