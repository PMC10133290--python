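import numpy as np
import pytest

from scratchkit.pipeline import PipelineConfig, preprocess_hand
from scratchkit.synthetic import (NightScenario, ScheduledEvent,
                                  simulate_night)


@pytest.fixture(scope="session")
def quiet_night():
    """Half-hour night with no events: gravity + noise only."""
    scen = NightScenario(duration_h=0.5, events=[], tso=(0.0, 1800.0), seed=11)
    return simulate_night(scen)


@pytest.fixture(scope="session")
def scratch_night():
    """Half-hour night with hand scratches and a posture movement."""
    scen = NightScenario(
        duration_h=0.5,
        events=[
            ScheduledEvent("scratch", 300.0, 315.0, "left",
                           {"freq_hz": 3.0, "amp_g": 0.5}),
            ScheduledEvent("non-scratch movement", 600.0, 612.0, "left"),
            ScheduledEvent("scratch", 900.0, 918.0, "right",
                           {"freq_hz": 3.5, "amp_g": 0.6}),
            ScheduledEvent("scratch", 1200.0, 1212.0, "left",
                           {"freq_hz": 2.5, "amp_g": 0.8}),
        ],
        tso=(0.0, 1800.0),
        seed=42,
    )
    return simulate_night(scen)


@pytest.fixture(scope="session")
def scratch_hand(scratch_night):
    """Preprocessed left hand of the scratch night (no calibration step)."""
    return preprocess_hand(scratch_night.recording_left,
                           PipelineConfig(calibrate=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
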