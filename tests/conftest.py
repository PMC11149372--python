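import numpy as np
import pytest
from hypothesis import settings
from threadpoolctl import threadpool_limits

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import equigen as eg
from equigen.cli import make_fixture


@pytest.fixture(scope="session", autouse=True)
def _single_threaded_blas():
    """Pin BLAS to one thread so trained weights are bit-reproducible."""
    with threadpool_limits(limits=1):
        yield


@pytest.fixture(scope="session")
def tiny_dataset() -> eg.MultiAncestryDataset:
    """200 EUR + 60 DDP individuals, 20 SNPs; shared across read-only tests."""
    return make_fixture("tiny", seed=42)


@pytest.fixture(scope="session")
def small_dataset() -> eg.MultiAncestryDataset:
    """600 EUR + 200 DDP, 50 SNPs; enough signal for learning-scheme tests."""
    return make_fixture("small", seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
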