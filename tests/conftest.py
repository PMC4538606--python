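import numpy as np
import pytest

from hglda import EntityId, FixtureSpec, SimilarityMatrix, generate_bipartite_fixture


def mirna(label: str) -> EntityId:
    return EntityId("mirna", label)


def disease(label: str) -> EntityId:
    return EntityId("disease", label)


def lncrna(label: str) -> EntityId:
    return EntityId("lncrna", label)


@pytest.fixture
def planted_fixture():
    """One seeded dataset with a single strongly planted pair (lnc00, disease00)."""
    spec = FixtureSpec(seed=7)
    return generate_bipartite_fixture(spec)


@pytest.fixture
def random_similarity():
    """A valid random symmetric similarity matrix over eight diseases."""
    rng = np.random.default_rng(11)
    entities = [disease(f"d{i}") for i in range(8)]
    values = rng.uniform(0.0, 1.0, size=(8, 8))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(entities=entities, values=values)
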