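import numpy as np
import pytest

from optimem import GroupLabels, TaxonomicProfile


def make_profile(matrix, prefix="t"):
    m = np.asarray(matrix, dtype=float)
    return TaxonomicProfile(
        abundance=m,
        sample_ids=[f"s{i + 1}" for i in range(m.shape[0])],
        taxon_ids=[f"{prefix}{j + 1}" for j in range(m.shape[1])],
    )


def two_groups(n_per_group):
    codes = np.repeat([0, 1], n_per_group)
    return GroupLabels(codes=codes, group_names=["g1", "g2"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_profile(rng):
    """20 samples x 8 taxa, two groups, taxa 0-1 differential (4x)."""
    mu = np.full(8, 100.0)
    counts = rng.poisson(mu, size=(20, 8)).astype(float)
    counts[10:, :2] *= 4.0
    return make_profile(counts), two_groups(10)
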