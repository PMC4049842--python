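import numpy as np
import pytest

import genonet as gn
from genonet.simulator import SimulationConfig


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    gn.make_fixtures(str(out), seed=0)
    return out


@pytest.fixture(scope="session")
def neutral_matrix():
    """Small three-population neutral sample shared across tests."""
    cfg = SimulationConfig(
        n_haplotypes_per_pop=200, region_length_bp=40_000, seed=12345
    )
    return gn.simulate_neutral(cfg)


@pytest.fixture(scope="session")
def neutral_scan(neutral_matrix):
    return gn.scan(neutral_matrix, k=11, step=1)


def random_haplotypes(rng, k, n):
    """n random binary strings of length k, biased toward shared variants."""
    freqs = rng.uniform(0.05, 0.95, size=k)
    block = (rng.random((n, k)) < freqs).astype(int)
    return ["".join(map(str, row)) for row in block]
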