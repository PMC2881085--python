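import numpy as np
import pytest

from decoyclust import make_ensemble, rmsd_matrix


def rank_signature(est):
    """Hashable full-ranking representation for exactness comparisons."""
    return [(r.rank, r.representative, tuple(r.members)) for r in est.ranking_]


@pytest.fixture(scope="session")
def small_ensemble():
    """100 decoys: 3 planted clusters of 30 plus 10 outliers, 40 residues."""
    return make_ensemble(seed=1)


@pytest.fixture(scope="session")
def small_matrix(small_ensemble):
    decoys, _ = small_ensemble
    return rmsd_matrix(decoys.coords)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
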