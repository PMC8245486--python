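import numpy as np
import pytest

from gutassembly import make_ground_truth, simulate_study


@pytest.fixture(scope="session")
def hierarchical_truth():
    """11-species hierarchical ground truth with study-default noise."""
    return make_ground_truth(11, mode="hierarchical", seed=11)


@pytest.fixture(scope="session")
def default_study(hierarchical_truth):
    """Full simulated study: 11 monocultures, 55 pairs, 20 trios, one octet."""
    return simulate_study(hierarchical_truth, seed=11)


@pytest.fixture(scope="session")
def noiseless_truth():
    """6-species truth with all observation noise switched off (exact fractions)."""
    return make_ground_truth(
        6,
        mode="hierarchical",
        params={"cv_total": 0.0, "colonies_counted": None, "epsilon_hoi": 0.0},
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_truth):
    return simulate_study(
        noiseless_truth,
        design={"trios": "all", "octet": None, "n_replicates": {"mono": 2, "pair": 2, "trio": 2}},
        seed=3,
    )
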