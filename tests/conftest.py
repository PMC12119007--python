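import numpy as np
import pytest

from basketopt import Scenario, TrialLayout


@pytest.fixture
def layout3() -> TrialLayout:
    """Three strata of 24 patients, uniform priors, target rate 0.2."""
    return TrialLayout(sample_sizes=(24, 24, 24), target_rates=(0.2,) * 3)


@pytest.fixture
def layout2_small() -> TrialLayout:
    """Two strata of 2 patients: 9 outcomes, hand-enumerable."""
    return TrialLayout(sample_sizes=(2, 2), target_rates=(0.2, 0.2))


@pytest.fixture
def scenario2() -> Scenario:
    """First stratum inactive at 0.2, second active at 0.5."""
    return Scenario(true_rates=(0.2, 0.5), active_set=frozenset([1]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
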