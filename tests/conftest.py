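import numpy as np
import pytest

import gaitvar as gv


@pytest.fixture
def he_profile():
    return gv.TABLE_PROFILES["HE"]


@pytest.fixture
def atx_profile():
    return gv.TABLE_PROFILES["ATX"]


@pytest.fixture
def md_trial():
    """One clean movement-disorders trial: 5 segments x 8 strides, 4 turns."""
    return gv.generate_trial(gv.TABLE_PROFILES["PD"], gv.md_config(), 42)


@pytest.fixture
def he_trial():
    """One clean healthy-elderly trial: 3 segments x 14 strides, 2 turns."""
    return gv.generate_trial(gv.TABLE_PROFILES["HE"], gv.he_config(), 42)


@pytest.fixture
def he_cohort_small():
    """20 healthy-elderly trials; enough for group statistics in tests."""
    return gv.generate_cohort([gv.TABLE_PROFILES["HE"]], {"HE": 20},
                              {"HE": gv.he_config()}, seed=3)


def segmented(trial, gap_factor=1.5):
    return gv.segment_by_turns(trial, gv.detect_turn_gaps(trial, gap_factor))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
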