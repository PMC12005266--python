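import numpy as np
import pytest

from assortmate.genome import GenomeMap


@pytest.fixture
def small_gmap() -> GenomeMap:
    """22 short chromosomes (total 2.2 Mb) for fast structural tests."""
    return GenomeMap(tuple(50_000 + 5_000 * i for i in range(22)), 1e-8)


@pytest.fixture
def hot_gmap() -> GenomeMap:
    """Short chromosomes with an exaggerated crossover rate so small
    simulations still produce several crossovers per chromosome."""
    return GenomeMap(tuple(50_000 + 5_000 * i for i in range(22)), 2e-5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
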