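import numpy as np
import pytest

from povdyn.rates import RateSet, Segment
from povdyn.synthetic import GroundTruth, PanelDesign, WavePlan, default_truth


@pytest.fixture(scope="session")
def truth_1x() -> GroundTruth:
    return default_truth("1x")


@pytest.fixture(scope="session")
def truth_2x() -> GroundTruth:
    return default_truth("2x")


@pytest.fixture
def random_rateset():
    """Factory for random valid annual-rate tables on a small age grid."""

    def make(ages=range(0, 5), seed=0, s_lo=0.5, s_hi=0.99):
        rng = np.random.default_rng(seed)
        n = len(list(ages))
        return RateSet.from_arrays(
            list(ages),
            s1=rng.uniform(s_lo, s_hi, n),
            s2=rng.uniform(s_lo, s_hi, n),
            t21=rng.uniform(0.05, 0.6, n),
            t22=rng.uniform(0.5, 0.99, n),
        )

    return make


@pytest.fixture
def single_segment():
    """One 12-month segment over ages 22-33 plus a design factory for it."""
    seg = Segment("solo", 22, 33, 12.0)

    def design(n_persons=500, waves=6, nonresponse=0.0, weight_sigma=0.0,
               initial_below=None, odds=1.0, interval_sd=1.0):
        return PanelDesign(
            plans=(WavePlan(seg, n_persons, waves, interval_sd),),
            nonresponse=nonresponse,
            below_nonresponse_odds=odds,
            weight_sigma=weight_sigma,
            initial_below=initial_below,
        )

    return seg, design
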