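import numpy as np
import pytest

from dysbionet import AbundanceProfile, OtuTable, distance_matrix, to_relative
from dysbionet.simulate import default_study_spec, generate_study


def random_profile(n_samples: int, n_otus: int, seed: int = 0) -> AbundanceProfile:
    """Random unit-scale abundance profile (strictly positive rows)."""
    rng = np.random.default_rng(seed)
    x = rng.random((n_samples, n_otus)) + 1e-3
    x /= x.sum(axis=1, keepdims=True)
    return AbundanceProfile(
        [f"s{i}" for i in range(n_samples)], [f"o{j}" for j in range(n_otus)], x
    )


def random_table(n_samples: int, n_otus: int, seed: int = 0, depth: int = 10_000) -> OtuTable:
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(n_otus), size=n_samples)
    counts = np.vstack([rng.multinomial(depth, row) for row in p])
    return OtuTable([f"s{i}" for i in range(n_samples)], [f"o{j}" for j in range(n_otus)], counts)


@pytest.fixture(scope="session")
def default_study():
    """One synthetic 7-cohort study (42 samples x 150 OTUs), shared read-only."""
    table, metadata, truth = generate_study(default_study_spec(seed=11))
    return table, metadata, truth


@pytest.fixture()
def small_profile():
    return random_profile(12, 20, seed=3)


@pytest.fixture()
def small_distance(small_profile):
    return distance_matrix(small_profile)
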