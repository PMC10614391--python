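import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mgaseq import BinnedGenome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_genome() -> BinnedGenome:
    """Two 1 Mb chromosomes at 100 kb bins: 20 bins total."""
    return BinnedGenome([("chr1", 1_000_000), ("chr2", 1_000_000)], 100_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
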