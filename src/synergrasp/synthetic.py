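"""Synthetic multi-subject grasp cohorts with known synergy structure.

The generator realizes the same model the analysis assumes. A fixed set of
orthonormal spatiotemporal synergies S (smooth random velocity curves)
defines the cohort's ground truth; every trial draws a weight vector c
from its grasp type's Gaussian profile and moves with velocity c^T S plus
additive noise, integrated to joint angles from a flat-hand 0 deg start.

On the neural side, scalp EEG carries an oscillatory background (pink
noise plus a 10 Hz resting rhythm with post-stimulus desynchronization
followed by synchronization) and a band-limited carrier per electrode
whose windowed band power equals an affine function of the trial's weight
vector: baseline + coupling @ c + noise. The carrier frequency (default
24 Hz, beta band) is an integer multiple of the sliding-window step rate,
so every 500 ms analysis window sees identical carrier samples and the
encoded band power is exact rather than approximate. The generator
calibrates carrier amplitudes against the package's own band-power
estimator, which makes the feature-encoding relation recoverable to
numerical precision when noise is switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import FeatureConfig, Protocol, SimulationParams
from .features import band_power
from .kinematics import unflatten_epoch
from .montage import CHANNEL_NAMES, POSITIONS, distances
from .sessions import Cohort, EEGSession, JOINT_LABELS, KinematicsSession

#: Band powers are clipped below at this floor (uV^2-scale units) so that
#: carrier amplitudes stay real; excursions reaching the floor are rare at
#: the default coupling scales.
FEATURE_FLOOR = 1.0

#: Share of signal energy carried by each of six synergies, engineered so
#: that under the default 10% velocity-noise budget the cumulative variance
#: passes the 85% selection threshold exactly at the sixth component
#: (cum-5 ~ 0.79, cum-6 ~ 0.90 of total variance).
DEFAULT_SIGNAL_FRACTIONS_6 = (
    0.26667, 0.18889, 0.16111, 0.13889, 0.12222, 0.12222,
)


def _default_fractions(n_syn: int) -> np.ndarray:
    if n_syn == 6:
        f = np.array(DEFAULT_SIGNAL_FRACTIONS_6)
    else:
        f = 0.8 ** np.arange(n_syn)
    return f / f.sum()


@dataclass
class GroundTruth:
    """Generative parameters shared by all subjects of one cohort."""

    synergies: np.ndarray        # [n_syn x (n_joints * epoch_samples)]
    weight_means: np.ndarray     # [n_grasps x n_syn]
    weight_cov: np.ndarray       # [n_syn x n_syn], symmetric PSD
    coupling: np.ndarray         # [n_electrodes x n_syn], non-negative
    feature_baseline: np.ndarray  # [n_electrodes], positive
    noise_sd_kin: float
    noise_sd_feat: float
    carrier_hz: float
    seed: int
    n_joints: int
    epoch_samples: int
    signal_fractions: np.ndarray
    coupling_centers: tuple[int, ...] = ()
    params: SimulationParams = field(default_factory=SimulationParams)

    @property
    def n_syn(self) -> int:
        return self.synergies.shape[0]

    @property
    def n_grasps(self) -> int:
        return self.weight_means.shape[0]

    def feature_means(self, c: np.ndarray) -> np.ndarray:
        """Noise-free per-electrode band-power targets for weights ``c``."""
        return np.maximum(self.feature_baseline + self.coupling @ np.asarray(c),
                          FEATURE_FLOOR)


def _smooth_orthonormal_rows(rng: np.random.Generator, n_rows: int,
                             n_joints: int, epoch_samples: int) -> np.ndarray:
    """Orthonormalized smooth random velocity curves, one row per synergy."""
    raw = rng.standard_normal((n_rows, n_joints, epoch_samples))
    sigma = max(epoch_samples / 15.0, 1.0)
    raw = gaussian_filter1d(raw, sigma=sigma, axis=-1, mode="constant")
    flat = raw.reshape(n_rows, -1)
    # QR of the transpose orthonormalizes the rows while keeping each
    # row's smooth character (Gram-Schmidt against earlier rows).
    Q, R = np.linalg.qr(flat.T)
    rows = (Q * np.sign(np.diag(R))).T
    for i in range(n_rows):
        k = int(np.argmax(np.abs(rows[i])))
        if rows[i, k] < 0:
            rows[i] *= -1.0
    return rows


def make_ground_truth(
    n_syn: int,
    n_joints: int = 10,
    epoch_samples: int = 250,
    n_grasps: int = 6,
    seed: int = 0,
    params: SimulationParams | None = None,
    feature_cfg: FeatureConfig | None = None,
) -> GroundTruth:
    """Draw a cohort-level ground truth (deterministic given ``seed``).

    Synergy rows are orthonormal smooth random curves. Per-grasp mean
    weights are rescaled exactly so that each synergy carries its assigned
    share of the total signal energy, split ``1 - within_grasp_frac`` /
    ``within_grasp_frac`` between across-grasp mean structure and
    within-grasp covariance. The EEG coupling concentrates each synergy on
    a contiguous electrode neighborhood (Gaussian fall-off around a random
    center electrode, distinct per synergy).
    """
    params = params or SimulationParams()
    if n_syn < 1:
        raise ValueError("n_syn must be >= 1")
    if n_syn > n_joints * epoch_samples:
        raise ValueError(
            f"n_syn={n_syn} exceeds the rank bound "
            f"{n_joints}*{epoch_samples}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    synergies = _smooth_orthonormal_rows(rng, n_syn, n_joints, epoch_samples)

    fractions = _default_fractions(n_syn)
    rms = params.weight_scale * np.sqrt(fractions)   # per-synergy weight RMS
    within = params.within_grasp_frac
    Z = rng.standard_normal((n_grasps, n_syn))
    if n_grasps >= n_syn:
        # Orthogonalize the grasp-mean columns so the weight second-moment
        # matrix is diagonal: each synergy then carries exactly its
        # designed share of signal energy and the cumulative-variance
        # structure of the cohort is guaranteed, not just approximate.
        Z, _ = np.linalg.qr(Z)
        Z = Z * np.sqrt(n_grasps)  # unit mean-square columns
        weight_means = Z * np.sqrt(1.0 - within) * rms
    else:
        col_ms = np.sqrt(np.mean(Z ** 2, axis=0))
        col_ms[col_ms == 0] = 1.0
        weight_means = Z / col_ms * np.sqrt(1.0 - within) * rms
    weight_cov = np.diag(within * rms ** 2)

    n_elec = len(CHANNEL_NAMES)
    centers = rng.choice(n_elec, size=min(n_syn, n_elec), replace=False)
    if n_syn > n_elec:  # degenerate configs reuse centers
        extra = rng.choice(n_elec, size=n_syn - n_elec, replace=True)
        centers = np.concatenate([centers, extra])
    dist = distances(POSITIONS)
    coupling = np.zeros((n_elec, n_syn))
    for j, ce in enumerate(centers):
        g = np.exp(-dist[ce] ** 2 / 2.0)
        g[dist[ce] > 2.0] = 0.0
        coupling[:, j] = g * params.coupling_peak / (rms[j] * g.max())
    baseline = np.full(n_elec, params.feature_baseline)

    return GroundTruth(
        synergies=synergies,
        weight_means=weight_means,
        weight_cov=weight_cov,
        coupling=coupling,
        feature_baseline=baseline,
        noise_sd_kin=params.noise_sd_kin,
        noise_sd_feat=params.noise_sd_feat,
        carrier_hz=params.carrier_hz,
        seed=seed,
        n_joints=n_joints,
        epoch_samples=epoch_samples,
        signal_fractions=fractions,
        coupling_centers=tuple(int(c) for c in centers),
        params=params,
    )


def _alpha_envelope(n: int, rate: float, onsets_s: np.ndarray,
                    epoch_s: float) -> np.ndarray:
    """Resting-rhythm amplitude envelope with post-stimulus ERD then ERS.

    Amplitude drops to 40% for ~0.5 s after each cue (desynchronization),
    rebounds to 150% until ~1.6 s (synchronization), then relaxes to the
    resting level; ramps are linear over 0.1 s.
    """
    t = np.arange(n) / rate
    env = np.ones(n)
    for t0 in onsets_s:
        erd = np.clip((t - t0) / 0.1, 0, 1) * np.clip((t0 + 0.5 - t) / 0.1, 0, 1)
        ers = np.clip((t - t0 - 0.5) / 0.1, 0, 1) * np.clip(
            (t0 + min(1.6, epoch_s) - t) / 0.1, 0, 1)
        env += -0.6 * np.minimum(erd, 1) + 0.5 * np.minimum(ers, 1)
    return np.clip(env, 0.0, None)


def _pink_noise(rng: np.random.Generator, n: int, n_ch: int,
                rate: float) -> np.ndarray:
    """Unit-RMS 1/f-shaped noise, [n x n_ch]."""
    white = rng.standard_normal((n, n_ch))
    F = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    F *= 1.0 / np.sqrt(np.maximum(f, 1.0))[:, None]
    x = np.fft.irfft(F, n, axis=0)
    x /= x.std(axis=0, keepdims=True)
    return x


def _draw_trials(rng: np.random.Generator, gt: GroundTruth,
                 protocol: Protocol) -> tuple[np.ndarray, np.ndarray]:
    """Grasp schedule and per-trial ground-truth weight matrix.

    Drawn first from the subject stream, so :func:`true_weights` can
    replay them independently of the downstream noise draws.
    """
    grasps = rng.permutation(np.repeat(np.arange(1, protocol.n_grasps + 1),
                                       protocol.n_reps))
    L = np.linalg.cholesky(gt.weight_cov + 1e-12 * np.eye(gt.n_syn))
    C = gt.weight_means[grasps - 1] + rng.standard_normal(
        (protocol.n_trials, gt.n_syn)) @ L.T
    return grasps, C


def true_weights(gt: GroundTruth, protocol: Protocol,
                 subject_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Replay the (grasp schedule, weight matrix) a subject was built from."""
    rng = np.random.default_rng(np.random.SeedSequence((gt.seed, subject_seed)))
    return _draw_trials(rng, gt, protocol)


def generate_subject(
    gt: GroundTruth,
    protocol: Protocol | None = None,
    subject_seed: int = 0,
    subject: str | None = None,
    feature_cfg: FeatureConfig | None = None,
) -> tuple[KinematicsSession, EEGSession]:
    """One subject's paired kinematic and EEG sessions.

    The random stream is derived from ``(gt.seed, subject_seed)`` so
    subjects are independent but reproducible. Grasp order is randomized;
    each grasp appears ``protocol.n_reps`` times.
    """
    protocol = protocol or Protocol(n_grasps=gt.n_grasps)
    feature_cfg = feature_cfg or FeatureConfig()
    if protocol.n_grasps != gt.n_grasps:
        raise ValueError("protocol n_grasps differs from ground truth")
    if protocol.kin_epoch_samples != gt.epoch_samples:
        raise ValueError(
            f"protocol epoch of {protocol.kin_epoch_samples} kinematic "
            f"samples differs from ground truth ({gt.epoch_samples})"
        )
    rng = np.random.default_rng(np.random.SeedSequence((gt.seed, subject_seed)))
    p = gt.params

    # --- trial schedule and weights -------------------------------------
    n_trials = protocol.n_trials
    grasps, C = _draw_trials(rng, gt, protocol)
    trial_len = protocol.epoch_s + protocol.iti_s
    onsets_s = protocol.rest_s + np.arange(n_trials) * trial_len
    events = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "grasp": grasps,
            "cue_on_s": onsets_s,
            "cue_off_s": onsets_s + protocol.epoch_s,
            "excluded": False,
        }
    )

    synergies = gt.synergies
    if p.subject_perturbation > 0:
        jitter = _smooth_orthonormal_rows(rng, gt.n_syn, gt.n_joints,
                                          gt.epoch_samples)
        mixed = synergies + p.subject_perturbation * jitter
        Q, R = np.linalg.qr(mixed.T)
        synergies = (Q * np.sign(np.diag(R))).T

    # --- kinematics: velocities -> angles -------------------------------
    kin_rate = protocol.kin_rate
    kin_epoch = protocol.kin_epoch_samples
    n_iti = int(round(protocol.iti_s * kin_rate))
    duration_s = protocol.rest_s + n_trials * trial_len
    n_vel = int(round(duration_s * kin_rate))
    vel = np.zeros((n_vel, gt.n_joints))
    rows = C @ synergies
    for k in range(n_trials):
        epoch_vel = unflatten_epoch(rows[k], gt.epoch_samples, gt.n_joints)
        if gt.noise_sd_kin > 0:
            epoch_vel = epoch_vel + gt.noise_sd_kin * rng.standard_normal(
                epoch_vel.shape)
        o = int(round(onsets_s[k] * kin_rate))
        vel[o:o + kin_epoch] = epoch_vel
        if n_iti > 0:  # constant-velocity return to the flat 0 deg posture
            drift = epoch_vel.sum(axis=0) / kin_rate
            vel[o + kin_epoch:o + kin_epoch + n_iti] = -drift * kin_rate / n_iti
    angles = np.vstack([np.zeros((1, gt.n_joints)),
                        np.cumsum(vel / kin_rate, axis=0)])

    kin = KinematicsSession(angles=angles, rate=kin_rate, events=events,
                            joint_labels=JOINT_LABELS[:gt.n_joints],
                            subject=subject)

    # --- EEG: background + calibrated band-power carrier ----------------
    eeg_rate = protocol.eeg_rate
    n_eeg = int(round(duration_s * eeg_rate))
    n_elec = gt.coupling.shape[0]
    data = np.zeros((n_eeg, n_elec))
    if p.background_scale > 0:
        pink = 2.0 * _pink_noise(rng, n_eeg, n_elec, eeg_rate)
        white = 0.5 * rng.standard_normal((n_eeg, n_elec))
        env = _alpha_envelope(n_eeg, eeg_rate, onsets_s, protocol.epoch_s)
        t = np.arange(n_eeg) / eeg_rate
        amp = 3.0 * (0.8 + 0.4 * rng.random(n_elec))
        phase = rng.uniform(0, 2 * np.pi, n_elec)
        alpha = (amp[None, :] * env[:, None]
                 * np.sin(2 * np.pi * 10.0 * t[:, None] + phase[None, :]))
        data += p.background_scale * (pink + white + alpha)

    eeg_epoch = protocol.eeg_epoch_samples
    width, _ = feature_cfg.window_samples(eeg_rate)
    for k in range(n_trials):
        targets = gt.feature_baseline + gt.coupling @ C[k]
        if gt.noise_sd_feat > 0:
            targets = targets + gt.noise_sd_feat * rng.standard_normal(n_elec)
        targets = np.maximum(targets, FEATURE_FLOOR)
        o = int(round(onsets_s[k] * eeg_rate))
        t_epoch = np.arange(o, o + eeg_epoch) / eeg_rate
        phases = rng.uniform(0, 2 * np.pi, n_elec)
        unit = np.sin(2 * np.pi * gt.carrier_hz * t_epoch[None, :width]
                      + phases[:, None])
        # calibrate against the package's own estimator so the measured
        # windowed band power equals the target exactly
        q = band_power(unit, eeg_rate, feature_cfg.band,
                       average=feature_cfg.average)
        if np.any(q <= 0):
            raise ValueError(
                f"carrier at {gt.carrier_hz} Hz has no power inside the "
                f"feature band {feature_cfg.band}"
            )
        amp_e = np.sqrt(targets / q)
        data[o:o + eeg_epoch] += (
            amp_e[:, None] * np.sin(2 * np.pi * gt.carrier_hz
                                    * t_epoch[None, :] + phases[:, None])
        ).T

    rest_samples = int(round(protocol.rest_s * eeg_rate))
    eeg = EEGSession(data=data, rate=eeg_rate, events=events.copy(),
                     channel_names=CHANNEL_NAMES, positions=POSITIONS.copy(),
                     resting_segment=(0, rest_samples), subject=subject)
    return kin, eeg


def generate_cohort(
    gt: GroundTruth,
    n_subjects: int,
    protocol: Protocol | None = None,
    seed: int = 0,
    feature_cfg: FeatureConfig | None = None,
) -> Cohort:
    """A cohort of independent subjects sharing one ground truth.

    Cross-subject generalization in this model is a property of the shared
    synergy structure: subjects differ only in their random trial weights,
    noise and background. Deterministic given ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a train/test split")
    protocol = protocol or Protocol(n_grasps=gt.n_grasps)
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_subjects)
    subjects = [
        generate_subject(gt, protocol, subject_seed=int(s),
                         subject=f"sub-{i + 1:02d}", feature_cfg=feature_cfg)
        for i, s in enumerate(sub_seeds)
    ]
    return Cohort(subjects=subjects, protocol=protocol, ground_truth=gt)
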