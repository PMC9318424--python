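"""In-memory containers for recorded sessions and multi-subject cohorts.

A trial/event table is a pandas DataFrame with columns

    trial_id   int, unique, 0-based
    grasp      int in 1..n_grasps (grasp-type label)
    cue_on_s   float, cue onset in session time (seconds)
    cue_off_s  float, cue offset
    excluded   bool, artifact-rejection mask (True = dropped downstream)

shared verbatim between the kinematic and EEG streams of one subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .config import Protocol
from .montage import CHANNEL_NAMES, POSITIONS

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import GroundTruth

#: The ten measured hand joints in fixed column order: MCP and IP of the
#: thumb, then MCP and PIP of index, middle, ring and pinky fingers.
JOINT_LABELS: tuple[str, ...] = (
    "TMCP", "TIP", "IMCP", "IPIP", "MMCP",
    "MPIP", "RMCP", "RPIP", "PMCP", "PPIP",
)

EVENT_COLUMNS = ("trial_id", "grasp", "cue_on_s", "cue_off_s", "excluded")


def validate_events(events: pd.DataFrame, duration_s: float | None = None) -> None:
    """Check the event-table schema and timing invariants."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    on = events["cue_on_s"].to_numpy(float)
    if len(on) > 1 and not np.all(np.diff(on) > 0):
        raise ValueError("cue onsets must be strictly increasing")
    if np.any(events["cue_off_s"].to_numpy(float) < on):
        raise ValueError("cue_off_s earlier than cue_on_s")
    if duration_s is not None and len(on) and (
        on[0] < 0 or events["cue_off_s"].to_numpy(float)[-1] > duration_s
    ):
        raise ValueError("event times outside the recording span")


@dataclass
class KinematicsSession:
    """One subject's joint-angle recording with cue events.

    angles : [samples x 10] joint angles in degrees
    rate   : sampling rate, Hz (125 in the emulated protocol)
    """

    angles: np.ndarray
    rate: float
    events: pd.DataFrame
    joint_labels: tuple[str, ...] = JOINT_LABELS
    subject: Optional[str] = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, float)
        if self.angles.ndim != 2 or self.angles.shape[1] != len(self.joint_labels):
            raise ValueError(
                f"angles must be [samples x {len(self.joint_labels)}], "
                f"got {self.angles.shape}"
            )
        validate_events(self.events, self.duration_s)

    @property
    def n_samples(self) -> int:
        return self.angles.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class EEGSession:
    """One subject's multi-channel EEG with montage and cue events.

    data            : [samples x 32] scalp potentials, uV
    rate            : sampling rate, Hz (256 in the emulated protocol)
    resting_segment : (start, stop) sample range of quiet baseline
    """

    data: np.ndarray
    rate: float
    events: pd.DataFrame
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    positions: np.ndarray = field(default_factory=lambda: POSITIONS.copy())
    resting_segment: tuple[int, int] = (0, 0)
    subject: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"data must be [samples x {len(self.channel_names)}], "
                f"got {self.data.shape}"
            )
        validate_events(self.events, self.duration_s)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def resting_data(self) -> np.ndarray:
        a, b = self.resting_segment
        return self.data[a:b]


@dataclass
class Cohort:
    """A list of paired (kinematics, EEG) sessions sharing one protocol."""

    subjects: list[tuple[KinematicsSession, EEGSession]]
    protocol: Protocol
    ground_truth: Optional["GroundTruth"] = None

    def __post_init__(self) -> None:
        for kin, eeg in self.subjects:
            if len(kin.events) != len(eeg.events):
                raise ValueError("kinematic and EEG event tables differ in length")
            if len(kin.events) != self.protocol.n_trials:
                raise ValueError(
                    f"subject has {len(kin.events)} cue events, protocol "
                    f"requires {self.protocol.n_trials}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list[str]:
        return [
            kin.subject or f"sub-{i + 1:02d}"
            for i, (kin, _) in enumerate(self.subjects)
        ]
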