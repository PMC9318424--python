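"""Run-time configuration objects shared across the pipeline.

All protocol constants default to the recording conditions the package
emulates: 6 grasp types x 30 repetitions per subject, hand kinematics
sampled at 125 Hz, 32-channel EEG at 256 Hz, 2 s post-cue epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import yaml

#: Frequency bands (Hz) used for band-restricted features and modulation
#: maps. Mu and beta follow the sensorimotor-rhythm convention (8-12 and
#: 18-30 Hz); delta/theta are the usual clinical bands and gamma is capped
#: by the 56 Hz analysis filter. 12-18 Hz belongs to no named band and is
#: covered only by the full-band feature set.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.1, 4.0),
    "theta": (4.0, 8.0),
    "mu": (8.0, 12.0),
    "beta": (18.0, 30.0),
    "gamma": (30.0, 56.0),
}

#: Full analysis band matching the pre-processing band-pass filter.
FULL_BAND: tuple[float, float] = (0.1, 56.0)


@dataclass(frozen=True)
class Protocol:
    """Recording protocol constants for one cohort.

    ``rest_s`` seconds of quiet baseline open each session; trials then
    follow as ``epoch_s`` of movement plus ``iti_s`` of return-to-rest.
    """

    n_grasps: int = 6
    n_reps: int = 30
    kin_rate: float = 125.0
    eeg_rate: float = 256.0
    epoch_s: float = 2.0
    rest_s: float = 4.0
    iti_s: float = 1.0

    def __post_init__(self) -> None:
        if self.n_grasps < 1 or self.n_reps < 1:
            raise ValueError("n_grasps and n_reps must be >= 1")
        if self.epoch_s <= 0 or self.kin_rate <= 0 or self.eeg_rate <= 0:
            raise ValueError("rates and epoch duration must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_grasps * self.n_reps

    @property
    def kin_epoch_samples(self) -> int:
        return int(round(self.epoch_s * self.kin_rate))

    @property
    def eeg_epoch_samples(self) -> int:
        return int(round(self.epoch_s * self.eeg_rate))


@dataclass(frozen=True)
class FeatureConfig:
    """Spectral-feature extraction settings.

    width_ms/overlap_ms
        Sliding-window geometry inside the post-cue epoch. The defaults
        (500 ms window, 375 ms overlap, i.e. 125 ms step) give 13 windows
        in a 2 s epoch at 256 Hz.
    band
        Frequency interval (Hz) over which the per-window power spectral
        density is integrated.
    average
        If True (default) the band integral is divided by the band width,
        giving a mean in-band power density; if False the raw integral
        (units uV^2) is used.
    log
        Optional log10 transform of the power features.
    pca_rule
        Retained-variance fraction (float in (0, 1)) or fixed component
        count (int) for the cross-electrode PCA reduction.
    """

    width_ms: float = 500.0
    overlap_ms: float = 375.0
    band: tuple[float, float] = FULL_BAND
    epoch_s: float = 2.0
    average: bool = True
    log: bool = False
    pca_rule: float | int = 0.9

    def window_samples(self, rate: float) -> tuple[int, int]:
        """(width, step) in samples at ``rate``."""
        width = int(round(self.width_ms * rate / 1000.0))
        overlap = int(round(self.overlap_ms * rate / 1000.0))
        return width, width - overlap


@dataclass(frozen=True)
class SimulationParams:
    """Generative model settings for the synthetic cohort.

    The defaults are the package's documented study conditions; see
    docs/methods.md for the signal-to-noise budget behind them.
    """

    n_syn: int = 6
    n_subjects: int = 10
    noise_sd_kin: float = 10.0       # additive velocity noise, deg/s
    noise_sd_feat: float = 1.5       # additive band-power noise, uV^2
    weight_scale: float = 1500.0     # RMS synergy-weight scale
    within_grasp_frac: float = 0.3   # share of weight energy within-grasp
    coupling_peak: float = 6.0       # peak feature gain, uV^2 per weight RMS
    feature_baseline: float = 25.0   # resting band power per electrode, uV^2
    carrier_hz: float = 24.0         # encoding carrier frequency (beta band)
    background_scale: float = 1.0    # multiplier on pink + alpha background
    subject_perturbation: float = 0.0  # per-subject synergy jitter (off)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (synthesize -> features -> decode -> evaluate)."""

    protocol: Protocol = field(default_factory=Protocol)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    synergy_threshold: float = 0.85
    n_folds: int = 10
    seed: int = 0
    compute_independency: bool = True
    compute_band_maps: bool = True
    neighborhood_radius: float = 1.2

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "protocol" in d:
            d["protocol"] = Protocol(**d["protocol"])
        if "features" in d:
            fd = dict(d["features"])
            if "band" in fd:
                fd["band"] = tuple(fd["band"])
            d["features"] = FeatureConfig(**fd)
        if "simulation" in d:
            d["simulation"] = SimulationParams(**d["simulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)
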