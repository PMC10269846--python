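import numpy as np
import pytest

from coretier import (
    CountTable,
    MetaCommunitySpec,
    hellinger,
    simulate_metacommunity,
    simulate_subcommunities,
    subcommunities_by_site,
    threshold_sweep,
)


@pytest.fixture
def small_counts() -> CountTable:
    counts = np.array(
        [
            [5, 0, 3, 12],
            [1, 1, 2, 0],
            [0, 4, 4, 8],
        ]
    )
    return CountTable(["s1", "s2", "s3"], ["tA", "tB", "tC", "tD"], counts)


@pytest.fixture(scope="session")
def planted_metacommunity():
    """Default planted meta-community: 5 sites x 30 samples, 5 core / 3 epidemic / 200 rare."""
    spec = MetaCommunitySpec(seed=11)
    return simulate_metacommunity(spec)


@pytest.fixture(scope="session")
def planted_sweep(planted_metacommunity):
    table, meta, truth = planted_metacommunity
    abundance = hellinger(table)
    real = subcommunities_by_site(table, meta)
    sim = simulate_subcommunities(table, n_samples=30, reps=100, seed=77)
    return threshold_sweep(real, sim, abundance), truth
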