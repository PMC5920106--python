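import numpy as np
import pandas as pd
import pytest

from alphap1 import EpochSet, default_montage
from alphap1.synthetic import desk_scale_config


@pytest.fixture(scope="session")
def montage60():
    return default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, sfreq=500.0, montage=None, t0=-200.0, target_ms=0.0,
                conditions=None, units="uV"):
    """Small EpochSet around an arbitrary data tensor (times relative to cue)."""
    n_trials, n_ch, n_samp = data.shape
    montage = montage or default_montage().subset(
        ["PO3", "P3", "P7", "P9", "O1", "PO4", "P4", "P8", "P10", "O2"][:n_ch])
    times = t0 + (1000.0 / sfreq) * np.arange(n_samp)
    if conditions is None:
        conditions = ["trained" if i % 2 == 0 else "untrained"
                      for i in range(n_trials)]
    labels = pd.DataFrame({
        "subject": 0,
        "condition": conditions,
        "trial_type": ["identical"] * n_trials,
    })
    return EpochSet(data=data, times_ms=times, sfreq=sfreq,
                    target_time_ms=target_ms, labels=labels, montage=montage,
                    units=units)


@pytest.fixture()
def tiny_config():
    """Very small cohort for fast end-to-end runs."""
    return desk_scale_config(seed=42, n_subjects=4, trials_per_condition=6)
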