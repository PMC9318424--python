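"""Shared fixtures: ground truths and cohorts at several noise settings.

Expensive cohorts are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synergrasp.config import FeatureConfig, Protocol, SimulationParams
from synergrasp.sessions import EEGSession
from synergrasp.synthetic import generate_cohort, make_ground_truth

NOISELESS = SimulationParams(noise_sd_kin=0.0, noise_sd_feat=0.0,
                             background_scale=0.0)


@pytest.fixture(scope="session")
def default_protocol() -> Protocol:
    return Protocol()


@pytest.fixture(scope="session")
def tiny_protocol() -> Protocol:
    return Protocol(n_reps=8)


@pytest.fixture(scope="session")
def gt_default(default_protocol):
    return make_ground_truth(6, 10, default_protocol.kin_epoch_samples, 6,
                             seed=7, params=SimulationParams())


@pytest.fixture(scope="session")
def cohort3(gt_default, default_protocol):
    """Three full-protocol subjects at the default noise setting."""
    return generate_cohort(gt_default, 3, default_protocol, seed=11)


@pytest.fixture(scope="session")
def default_subject(cohort3):
    """One full-protocol subject (kinematics, EEG)."""
    return cohort3.subjects[0]


@pytest.fixture(scope="session")
def gt_noiseless(tiny_protocol):
    return make_ground_truth(6, 10, tiny_protocol.kin_epoch_samples, 6,
                             seed=7, params=NOISELESS)


@pytest.fixture(scope="session")
def cohort_noiseless(gt_noiseless, tiny_protocol):
    """Two noiseless subjects, 6 grasps x 8 reps."""
    return generate_cohort(gt_noiseless, 2, tiny_protocol, seed=3)


@pytest.fixture(scope="session")
def feature_cfg() -> FeatureConfig:
    return FeatureConfig()


def make_test_eeg(data: np.ndarray, rate: float = 256.0,
                  resting: tuple[int, int] = (0, 256),
                  cue_on_s: float | None = None) -> EEGSession:
    """Wrap a raw [samples x 32] array into a session with one event."""
    n = data.shape[0]
    if cue_on_s is None:
        cue_on_s = resting[1] / rate
    events = pd.DataFrame(
        {"trial_id": [0], "grasp": [1], "cue_on_s": [cue_on_s],
         "cue_off_s": [min(cue_on_s + 2.0, n / rate)], "excluded": [False]}
    )
    return EEGSession(data=data, rate=rate, events=events,
                      resting_segment=resting)
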