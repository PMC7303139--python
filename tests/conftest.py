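import numpy as np
import pytest

from leechmine.scoring import ScoringScheme
from leechmine.simulate import SimConfig, plant_genome


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact planted-family bundle shared by read-only tests."""
    cfg = SimConfig(seed=42, n_families=2, archetype_length=200, cys_count=8,
                    copies_per_family=4, tandem_fraction=0.5, divergence_t=0.05,
                    n_decoys=10, n_scaffolds=4)
    return plant_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
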