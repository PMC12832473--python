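import os
import sys

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from hhineq.survey_core import OUTCOME, WEIGHT  # noqa: E402
from hhineq.synthetic_survey import DEFAULT_WAVE_CONFIGS, generate_wave  # noqa: E402


@pytest.fixture(scope="session")
def wave1_table():
    """One seeded wave-1 synthetic round at a reduced n (shared, read-only)."""
    cfg = DEFAULT_WAVE_CONFIGS["wave1"].replace(n=3000)
    return generate_wave(cfg, seed=11)


@pytest.fixture
def tiny_frame():
    """4-row minimal frame with distinct ses and equal weights."""
    return pd.DataFrame(
        {
            OUTCOME: [0.0, 0.0, 1.0, 1.0],
            "ses_score": [1.0, 2.0, 3.0, 4.0],
            WEIGHT: [1.0, 1.0, 1.0, 1.0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
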