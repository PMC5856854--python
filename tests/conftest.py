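import numpy as np
import pytest

from padif import AtomKey, AtomScoreTable, PADIF
from padif.io import N_TERMS


def make_atoms(n):
    return [AtomKey("A", i + 1, "", "CA") for i in range(n)]


def padif_from_matrix(values, source_id="p"):
    values = np.asarray(values, dtype=float)
    return PADIF(atoms=make_atoms(values.shape[0]), values=values,
                 source_id=source_id)


def table_from_matrix(values, source_id="t"):
    values = np.asarray(values, dtype=float)
    return AtomScoreTable(atoms=make_atoms(values.shape[0]), values=values,
                          source_id=source_id)


def random_padif(rng, n_atoms, p_neg=0.3, p_pos=0.2, source_id="p"):
    """Sparse random sign pattern with random magnitudes."""
    u = rng.random((n_atoms, N_TERMS))
    values = np.zeros((n_atoms, N_TERMS))
    values[u < p_neg] = -rng.random(np.count_nonzero(u < p_neg)) - 0.01
    hi = u > 1 - p_pos
    values[hi] = rng.random(np.count_nonzero(hi)) + 0.01
    return padif_from_matrix(values, source_id=source_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
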