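"""Joint-angle differentiation, trial segmentation and the velocity matrix.

One grasp trial contributes one row to the velocity matrix V: its 2 s
post-cue angular-velocity epoch, flattened joint-major (all samples of
joint 1, then joint 2, ...). Rows of V feed the synergy decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sessions import JOINT_LABELS, KinematicsSession


class SegmentationError(ValueError):
    """A trial epoch does not fit inside the recording."""

    def __init__(self, trial_id: int, message: str) -> None:
        self.trial_id = trial_id
        super().__init__(f"trial {trial_id}: {message}")


def angular_velocity(angles: np.ndarray, rate: float) -> np.ndarray:
    """First-order forward-difference angular velocity, deg/s.

    Output has one sample fewer than the input; sample k holds
    ``(angles[k+1] - angles[k]) * rate``.
    """
    a = np.asarray(angles, float)
    if a.shape[0] < 2:
        raise ValueError("need at least two samples to differentiate")
    return np.diff(a, axis=0) * rate


def segment_trials(
    session: KinematicsSession,
    epoch_s: float,
    velocities: np.ndarray | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Cue-aligned velocity epochs for every retained trial.

    Each epoch is a [epoch_samples x n_joints] block of angular velocities
    starting at the cue-onset sample (0-based, half-open). Trials flagged
    ``excluded`` are skipped. Returns the epochs and the matching rows of
    the event table.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    v = angular_velocity(session.angles, session.rate) if velocities is None \
        else np.asarray(velocities, float)
    epoch = int(round(epoch_s * session.rate))
    events = session.events
    keep = ~events["excluded"].to_numpy(bool)
    epochs: list[np.ndarray] = []
    for _, row in events[keep].iterrows():
        onset = int(round(row["cue_on_s"] * session.rate))
        if onset < 0 or onset + epoch > v.shape[0]:
            raise SegmentationError(
                int(row["trial_id"]),
                f"epoch [{onset}, {onset + epoch}) outside recording "
                f"of {v.shape[0]} velocity samples",
            )
        epochs.append(v[onset:onset + epoch])
    return epochs, events[keep].reset_index(drop=True)


def flatten_epoch(epoch: np.ndarray) -> np.ndarray:
    """[samples x joints] -> joint-major row of length joints*samples."""
    e = np.asarray(epoch, float)
    if e.ndim != 2:
        raise ValueError("epoch must be 2-D [samples x joints]")
    return e.T.reshape(-1)


def unflatten_epoch(row: np.ndarray, epoch_samples: int,
                    n_joints: int) -> np.ndarray:
    """Inverse of :func:`flatten_epoch`."""
    r = np.asarray(row, float)
    if r.size != epoch_samples * n_joints:
        raise ValueError(
            f"row of length {r.size} does not match "
            f"{n_joints} x {epoch_samples}"
        )
    return r.reshape(n_joints, epoch_samples).T


@dataclass
class VelocityMatrix:
    """Trials x concatenated-joint-velocity matrix V.

    V            : [m x (n_joints * epoch_samples)], joint-major rows
    trial_index  : one row per V row (subject, trial_id, grasp)
    """

    V: np.ndarray
    epoch_samples: int
    n_joints: int
    trial_index: pd.DataFrame
    joint_labels: tuple[str, ...] = JOINT_LABELS

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, float)
        if self.V.shape[1] != self.n_joints * self.epoch_samples:
            raise ValueError("V column count does not match the layout")
        if self.V.shape[0] != len(self.trial_index):
            raise ValueError("trial_index length does not match row count")

    @property
    def layout(self) -> dict:
        return {
            "order": "joint-major",
            "n_joints": self.n_joints,
            "epoch_samples": self.epoch_samples,
            "joint_labels": list(self.joint_labels),
        }

    def epoch(self, row: int) -> np.ndarray:
        return unflatten_epoch(self.V[row], self.epoch_samples, self.n_joints)


def build_velocity_matrix(
    epochs: Sequence[np.ndarray],
    trial_index: pd.DataFrame | None = None,
    joint_labels: tuple[str, ...] = JOINT_LABELS,
) -> VelocityMatrix:
    """Stack per-trial velocity epochs into the matrix V."""
    if len(epochs) == 0:
        raise ValueError("no epochs to stack")
    shape = np.asarray(epochs[0]).shape
    for i, e in enumerate(epochs):
        if np.asarray(e).shape != shape:
            raise ValueError(
                f"epoch {i} has shape {np.asarray(e).shape}, expected {shape}"
            )
    samples, joints = shape
    V = np.stack([flatten_epoch(e) for e in epochs])
    if trial_index is None:
        trial_index = pd.DataFrame(
            {"subject": "sub", "trial_id": np.arange(len(epochs)), "grasp": 0}
        )
    return VelocityMatrix(V=V, epoch_samples=samples, n_joints=joints,
                          trial_index=trial_index.reset_index(drop=True),
                          joint_labels=joint_labels[:joints])


def session_velocity_matrix(session: KinematicsSession,
                            epoch_s: float) -> VelocityMatrix:
    """Segment one session and assemble its velocity matrix."""
    epochs, events = segment_trials(session, epoch_s)
    idx = pd.DataFrame(
        {
            "subject": session.subject or "sub",
            "trial_id": events["trial_id"].to_numpy(),
            "grasp": events["grasp"].to_numpy(),
        }
    )
    return build_velocity_matrix(epochs, idx, session.joint_labels)


def cohort_velocity_matrix(
    sessions: Sequence[KinematicsSession], epoch_s: float
) -> VelocityMatrix:
    """Concatenate the velocity matrices of several subjects."""
    parts = [session_velocity_matrix(s, epoch_s) for s in sessions]
    first = parts[0]
    return VelocityMatrix(
        V=np.vstack([p.V for p in parts]),
        epoch_samples=first.epoch_samples,
        n_joints=first.n_joints,
        trial_index=pd.concat([p.trial_index for p in parts],
                              ignore_index=True),
        joint_labels=first.joint_labels,
    )
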