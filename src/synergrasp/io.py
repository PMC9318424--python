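"""Delimited-text readers and writers for sessions, cohorts and results.

Formats (all plain text):

- kinematics.csv : time_s + one column per joint (degrees), fixed order
- eeg.csv        : time_s + one column per channel (uV)
- events.csv     : trial_id, grasp, cue_on_s, cue_off_s, excluded
- montage.tsv    : name, x, y
- synergies.csv + synergies.json : selected synergy rows and their layout

EEG may also be supplied as European Data Format (read-only, via mne).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import montage_table
from .sessions import (Cohort, EEGSession, KinematicsSession,
                       validate_events)
from .synergy import SynergySet
from .config import Protocol


# --- kinematics -----------------------------------------------------------

def write_kinematics(session: KinematicsSession, path: str | Path) -> None:
    t = np.arange(session.n_samples) / session.rate
    df = pd.DataFrame(session.angles, columns=list(session.joint_labels))
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False, float_format="%.6f")


def read_kinematics(path: str | Path, events: pd.DataFrame,
                    rate: float | None = None,
                    calibration: pd.DataFrame | None = None,
                    subject: str | None = None) -> KinematicsSession:
    """Read a delimited joint-angle table.

    ``calibration`` may hold per-joint linear gain/offset columns
    (joint, gain, offset) applied as angle = gain * raw + offset.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("kinematics table must contain a time_s column")
    t = df["time_s"].to_numpy(float)
    joints = [c for c in df.columns if c != "time_s"]
    angles = df[joints].to_numpy(float)
    if calibration is not None:
        cal = calibration.set_index("joint")
        for j, name in enumerate(joints):
            if name in cal.index:
                angles[:, j] = (cal.at[name, "gain"] * angles[:, j]
                                + cal.at[name, "offset"])
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    return KinematicsSession(angles=angles, rate=rate, events=events,
                             joint_labels=tuple(joints), subject=subject)


# --- events ---------------------------------------------------------------

def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path)
    ev["excluded"] = ev["excluded"].astype(bool)
    validate_events(ev)
    return ev


# --- EEG ------------------------------------------------------------------

def write_eeg(session: EEGSession, path: str | Path) -> None:
    t = np.arange(session.n_samples) / session.rate
    df = pd.DataFrame(session.data, columns=list(session.channel_names))
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False, float_format="%.4f")


def read_eeg(path: str | Path, events: pd.DataFrame,
             rate: float | None = None,
             resting_segment: tuple[int, int] = (0, 0),
             subject: str | None = None) -> EEGSession:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("EEG table must contain a time_s column")
    t = df["time_s"].to_numpy(float)
    channels = [c for c in df.columns if c != "time_s"]
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    return EEGSession(data=df[channels].to_numpy(float), rate=rate,
                      events=events, channel_names=tuple(channels),
                      resting_segment=resting_segment, subject=subject)


def read_eeg_edf(path: str | Path, events: pd.DataFrame,
                 resting_segment: tuple[int, int] = (0, 0),
                 subject: str | None = None) -> EEGSession:
    """Read an EEG recording from European Data Format (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package "
                          "(install extra synergrasp[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts -> microvolts
    return EEGSession(data=data, rate=float(raw.info["sfreq"]),
                      events=events, channel_names=tuple(raw.ch_names),
                      resting_segment=resting_segment, subject=subject)


def write_montage(path: str | Path) -> None:
    montage_table().to_csv(path, sep="\t", index=False)


# --- cohorts --------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """One subdirectory per subject with kinematics/eeg/events tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_subjects": cohort.n_subjects,
        "protocol": {
            "n_grasps": cohort.protocol.n_grasps,
            "n_reps": cohort.protocol.n_reps,
            "kin_rate": cohort.protocol.kin_rate,
            "eeg_rate": cohort.protocol.eeg_rate,
            "epoch_s": cohort.protocol.epoch_s,
            "rest_s": cohort.protocol.rest_s,
            "iti_s": cohort.protocol.iti_s,
        },
        "subjects": cohort.subject_ids(),
    }
    (out / "cohort.json").write_text(json.dumps(meta, indent=2))
    write_montage(out / "montage.tsv")
    for sid, (kin, eeg) in zip(cohort.subject_ids(), cohort.subjects):
        d = out / sid
        d.mkdir(exist_ok=True)
        write_kinematics(kin, d / "kinematics.csv")
        write_eeg(eeg, d / "eeg.csv")
        write_events(kin.events, d / "events.csv")
        (d / "resting.json").write_text(
            json.dumps({"resting_segment": list(eeg.resting_segment)}))


def read_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    meta = json.loads((src / "cohort.json").read_text())
    protocol = Protocol(**meta["protocol"])
    subjects = []
    for sid in meta["subjects"]:
        d = src / sid
        events = read_events(d / "events.csv")
        rest = json.loads((d / "resting.json").read_text())["resting_segment"]
        kin = read_kinematics(d / "kinematics.csv", events,
                              rate=protocol.kin_rate, subject=sid)
        eeg = read_eeg(d / "eeg.csv", events, rate=protocol.eeg_rate,
                       resting_segment=tuple(rest), subject=sid)
        subjects.append((kin, eeg))
    return Cohort(subjects=subjects, protocol=protocol)


# --- synergies ------------------------------------------------------------

def write_synergies(sset: SynergySet, prefix: str | Path) -> None:
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".csv"), sset.S, delimiter=",")
    meta = {
        "n_syn": sset.n_syn,
        "epoch_samples": sset.epoch_samples,
        "n_joints": sset.n_joints,
        "joint_labels": list(sset.joint_labels),
        "threshold": sset.threshold,
        "variance_fractions": [float(v) for v in sset.variance_fractions],
        "layout": "joint-major",
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_synergies(prefix: str | Path) -> SynergySet:
    prefix = Path(prefix)
    S = np.atleast_2d(np.loadtxt(prefix.with_suffix(".csv"), delimiter=","))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return SynergySet(
        S=S, variance_fractions=np.array(meta["variance_fractions"]),
        threshold=meta["threshold"], epoch_samples=meta["epoch_samples"],
        n_joints=meta["n_joints"], joint_labels=tuple(meta["joint_labels"]),
    )
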