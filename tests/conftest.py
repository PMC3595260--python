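import logging

import numpy as np
import pytest

from speecherp import HeadModel, build_montage, simulate_recording
from speecherp.synth import ArtifactSpec, TrialSchedule, default_sources

# the rank-deficiency warnings from intentionally degenerate fixtures are
# expected; keep test output readable
logging.getLogger("speecherp.emgcca").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def montage():
    return build_montage("biosemi64", 10.0)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def sim_full(montage, head):
    """One contaminated synthetic subject (EMG + blinks + background)."""
    schedule = TrialSchedule(n_trials=40, seed=20)
    sources = default_sources(montage, head)
    rec, events, gt = simulate_recording(montage, head, sources,
                                         ArtifactSpec(), schedule)
    return rec, events, gt


@pytest.fixture(scope="session")
def sim_clean(montage, head):
    """Same subject without EMG or blinks (background + sensor noise only)."""
    schedule = TrialSchedule(n_trials=40, seed=20)
    sources = default_sources(montage, head)
    art = ArtifactSpec(emg_amplitude_uv=0.0, blink_rate_hz=0.0)
    rec, events, gt = simulate_recording(montage, head, sources, art, schedule)
    return rec, events, gt
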