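import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from thermoengage import SynthConfig, ThermalSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def quiet_config():
    """All randomness and artifacts switched off."""
    return SynthConfig(seed=0, n_subjects=2, noise_sd=0.0, outlier_rate=0.0,
                       gap_rate=0.0, drift_per_session=0.0, subject_sd=0.0)


@pytest.fixture
def noisy_config():
    """Study-condition defaults with artifacts on."""
    return SynthConfig(seed=42, n_subjects=3, outlier_rate=0.002)


def make_series(samples, rate=10.0, valid=None, **kw):
    return ThermalSeries(np.asarray(samples, dtype=float), rate, valid, **kw)


@pytest.fixture
def series_factory():
    return make_series
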