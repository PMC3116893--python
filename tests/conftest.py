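import numpy as np
import pytest

from modescope import nma
from modescope import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_chain():
    return sd.make_toy_chain(30, seed=1)


@pytest.fixture(scope="session")
def toy_modes(toy_chain):
    return nma.compute_enm_modes(toy_chain, cutoff=10.0, n_modes=None)


@pytest.fixture(scope="session")
def helix():
    return sd.make_ideal_helix(12)


@pytest.fixture(scope="session")
def cavity():
    return sd.make_cavity_structure(8.0, 40.0, 200, seed=1)


@pytest.fixture(scope="session")
def two_state_pair(toy_chain):
    """Chain plus an internally deformed partner at 8 Å fitted RMSD."""
    other = sd.make_deformed_state(toy_chain, 8.0, seed=7)
    return toy_chain, other


def random_unit_modes(n_modes, n_atoms, seed):
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((n_modes, 3 * n_atoms))
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
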