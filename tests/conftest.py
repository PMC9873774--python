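import numpy as np
import pytest

from ebrdt import (EEGSimConfig, PopulationSimConfig, ResponseSimConfig,
                   simulate_aut_responses, simulate_eeg, simulate_participants)

BLINK_TIMES_30 = list(np.arange(3.0, 180.0, 6.0)[:30])       # 10 blinks/min
SACCADE_TIMES_10 = list(np.arange(1.5, 60.0, 6.0)[:10])


@pytest.fixture(scope="session")
def noisy_recording():
    """180 s, 30 blinks + 10 saccade surrogates, SNR = 10 (amp 100, noise 10)."""
    cfg = EEGSimConfig(blink_times=BLINK_TIMES_30,
                       saccade_times=SACCADE_TIMES_10, seed=42)
    rec, gt = simulate_eeg(cfg)
    return rec, gt, cfg


@pytest.fixture(scope="session")
def clean_recording():
    cfg = EEGSimConfig(blink_times=BLINK_TIMES_30, noise_sd=0.0, seed=0)
    rec, gt = simulate_eeg(cfg)
    return rec, gt, cfg


@pytest.fixture(scope="session")
def participants():
    return simulate_participants(PopulationSimConfig(seed=7))


@pytest.fixture(scope="session")
def responses(participants):
    return simulate_aut_responses(participants, ResponseSimConfig(seed=8))
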