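import numpy as np
import pytest

from parascreen.containers import PeptideMultiset
from parascreen.reads import DemuxSpec
from parascreen.simulate import (
    DEFAULT_FLANK3,
    DEFAULT_FLANK5,
    NoiseModel,
    build_naive_population,
    sample_counts,
)

BARCODE = "ACGTAC"


@pytest.fixture
def spec():
    return DemuxSpec({"S1": BARCODE}, DEFAULT_FLANK5, DEFAULT_FLANK3)


@pytest.fixture
def small_multiset():
    return PeptideMultiset(
        {"AAAAAAA": 50, "CCCCCCC": 30, "DDDDDDD": 10, "EEEEEEE": 5,
         "FFFFFFF": 3, "GGGGGGG": 1, "HHHHHHH": 1},
        label="toy",
    )


@pytest.fixture
def naive_pop():
    return build_naive_population(2000, skew_sd=1.0, parasite_fraction=0.005,
                                  parasite_advantage=10.0, seed=11)


@pytest.fixture
def naive_counts(naive_pop):
    return sample_counts(naive_pop, 50_000, seed=12)


@pytest.fixture
def noiseless():
    return NoiseModel.noiseless()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
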