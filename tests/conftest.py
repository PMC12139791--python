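import numpy as np
import pytest

import connshift as cs
from connshift import pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """One 10-subject, 30-node cohort with planted effect, behavior and both
    rest and doors runs — shared by tests that only read it."""
    cfg = cs.SynthConfig(n_subjects=10, n_nodes=30, n_timepoints=120,
                         run_types=("rest", "doors"), include_behavior=True, seed=11)
    return cs.gen_condition_dataset(cfg)


@pytest.fixture(scope="session")
def small_rest_conns(small_dataset):
    return pipeline.dataset_connectomes(small_dataset, "rest")


def random_conn(rng, n_nodes, missing=()):
    """Random symmetric Fisher-z-like matrix with optional invalid nodes."""
    a = rng.normal(0, 0.5, size=(n_nodes, n_nodes))
    v = (a + a.T) / 2
    np.fill_diagonal(v, 0.0)
    valid = np.ones(n_nodes, dtype=bool)
    for i in missing:
        valid[i] = False
        v[i, :] = np.nan
        v[:, i] = np.nan
        v[i, i] = np.nan
    return cs.ConnMatrix(v, valid)


def random_mask(rng, n_nodes, n_edges, label="m"):
    iu = np.triu_indices(n_nodes, k=1)
    idx = rng.choice(iu[0].size, size=n_edges, replace=False)
    m = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    m[iu[0][idx], iu[1][idx]] = 1
    return cs.EdgeMask(m + m.T, label=label)
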