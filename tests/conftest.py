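import numpy as np
import pytest

from xtalbio.structure_io import Atom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_atoms(coords, element="C", radius=1.70, residue_indices=None):
    """Plain atoms at given coordinates, one residue per atom by default."""
    coords = np.asarray(coords, float)
    out = []
    for i, c in enumerate(coords):
        ridx = residue_indices[i] if residue_indices is not None else i
        out.append(Atom(serial=i + 1, element=element, name="X",
                        residue_index=ridx, coords=c, vdw_radius=radius))
    return out


@pytest.fixture(scope="session")
def small_crystal():
    """One modest P21 crystal with a small lattice interface, shared across
    tests that only read from it."""
    from xtalbio.fixtures import FixtureSpec, make_crystal_fixture

    spec = FixtureSpec(spacegroup_symbol="P 1 21 1", chain_length=18,
                       interface_target="SMALL", seed=7)
    return make_crystal_fixture(spec)
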