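import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from gknnqsar import ChemicalRecord, Dataset, SimilarityMatrix, SyntheticSpec, generate


def make_dataset(activities, ids=None, endpoint="activity", **extra):
    """Abstract dataset (no structures) from a list of activities."""
    ids = ids or [f"C{i}" for i in range(len(activities))]
    return Dataset(
        [
            ChemicalRecord(chem_id=cid, endpoint_scores={endpoint: float(a)}, **extra)
            for cid, a in zip(ids, activities)
        ],
        endpoint=endpoint,
    )


def make_self_matrix(values, ids):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(values=values, row_ids=list(ids), col_ids=list(ids))


def random_self_matrix(rng, n):
    """Random symmetric unit-diagonal similarity matrix in [0, 1)."""
    m = rng.uniform(0.0, 0.95, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


@pytest.fixture(scope="session")
def smiles_set():
    """Small real-structure smooth fixture, shared across tests."""
    ds, sm = generate(
        SyntheticSpec(
            n_chemicals=12, mode="real_smiles", landscape="smooth", n_actives=4, seed=11
        )
    )
    return ds, sm


@pytest.fixture(scope="session")
def abstract_smooth():
    ds, sm = generate(
        SyntheticSpec(
            n_chemicals=30,
            mode="abstract_matrix",
            landscape="smooth",
            n_actives=10,
            seed=5,
        )
    )
    return ds, sm
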