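import numpy as np
import pytest

from lcmds.io import DrugCatalog, InteractionMatrix, SimilarityMatrix
from lcmds.synthetic import SyntheticConfig, generate_synthetic_ddi


@pytest.fixture(scope="session")
def small_dataset():
    """Default-config planted dataset used across modules (60 drugs)."""
    return generate_synthetic_ddi(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A very small planted dataset for fast protocol tests (16 drugs)."""
    return generate_synthetic_ddi(SyntheticConfig(m=16, groups=2, seed=3))


def random_similarity(rng, m):
    """A random valid similarity matrix (symmetric, [0,1], unit diagonal)."""
    raw = rng.random((m, m))
    s = (raw + raw.T) / 2
    np.fill_diagonal(s, 1.0)
    return s


def two_block_network(n_per_cluster=6, within_sim=0.9, cross_sim=0.1):
    """Two similarity clusters; interactions only across clusters.

    Every drug in cluster 1 interacts with every drug in cluster 2 and
    with nothing in its own cluster, so a query similar to cluster-1
    drugs should score cluster-2 targets highest.
    """
    m = 2 * n_per_cluster
    cluster = np.repeat([0, 1], n_per_cluster)
    S = np.where(cluster[:, None] == cluster[None, :], within_sim, cross_sim)
    np.fill_diagonal(S, 1.0)
    A = (cluster[:, None] != cluster[None, :]).astype(int)
    np.fill_diagonal(A, 0)
    cat = DrugCatalog.from_ids(f"d{i}" for i in range(m))
    return (
        InteractionMatrix(cat, A),
        SimilarityMatrix(cat, S),
        cluster,
    )
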