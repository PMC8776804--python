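import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import phagetax as pt


@pytest.fixture(scope="session")
def small_community() -> pt.PlantedCommunity:
    """2 families x 1 genus x 2 species x 1 strain, 20-25 kb genomes."""
    spec = pt.CommunitySpec(
        seed=11, n_families=2, genera_per_family=1, species_per_genus=2,
        strains_per_species=1, genome_length_range=(20_000, 25_000),
    )
    return pt.plant_taxonomy(spec)


@pytest.fixture(scope="session")
def small_similarity(small_community) -> pt.SimilarityMatrix:
    return pt.similarity_matrix(small_community.genomes)


def random_distance_frame(n: int, seed: int):
    """Random symmetric distance matrix in [0, 1] with zero diagonal."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    D = rng.uniform(0.05, 1.0, size=(n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = [f"g{i:02d}" for i in range(n)]
    return pd.DataFrame(D, index=ids, columns=ids)
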