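import numpy as np
import pytest

from saxsfold import AtomicStructure, FixtureSpec, make_chain


@pytest.fixture(scope="session")
def globule30():
    """30-atom compact chain with generic (non-degenerate) pair distances."""
    return make_chain(FixtureSpec(kind="globule", n_residues=30, seed=1))


@pytest.fixture(scope="session")
def two_atom():
    """Two unit-Z atoms 10 A apart."""
    return AtomicStructure(
        elements=["H", "H"], z=np.array([1, 1]),
        coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]]),
        chain_ids=["A", "A"], res_indices=np.array([1, 2]),
        res_names=["GLY", "GLY"], atom_names=["CA", "CA"],
    )


@pytest.fixture(scope="session")
def q_grid():
    return np.linspace(0.0, 0.5, 51)
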