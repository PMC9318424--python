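"""EEG preprocessing and windowed spectral-power feature extraction.

The feature of record is the integral of the power spectral density over a
frequency band, computed in 500 ms Hann-tapered windows that slide with
75% overlap across the 2 s post-cue epoch (13 windows per electrode at
256 Hz). Features from all electrodes are optionally reduced with PCA
fitted on training trials only.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .config import FeatureConfig
from .sessions import EEGSession


class NotFittedError(RuntimeError):
    """A reducer was applied before being fitted."""


class LeakageError(RuntimeError):
    """A fitted parameter depends on rows outside the training fold."""


def preprocess(session: EEGSession, band: tuple[float, float] = (0.1, 56.0),
               order: int = 4) -> EEGSession:
    """Baseline-correct, detrend and band-pass filter a session.

    Per channel: subtract the mean of the resting segment, remove the
    linear trend, then apply a zero-phase (forward-backward) Butterworth
    band-pass of the given order between ``band`` Hz. The sampling rate is
    unchanged.
    """
    rest = session.resting_data()
    if rest.size == 0:
        raise ValueError("session has an empty resting segment")
    x = session.data - rest.mean(axis=0)
    x = signal.detrend(x, axis=0, type="linear")
    sos = signal.butter(order, band, btype="bandpass", fs=session.rate,
                        output="sos")
    x = signal.sosfiltfilt(sos, x, axis=0)
    return EEGSession(
        data=x, rate=session.rate, events=session.events,
        channel_names=session.channel_names, positions=session.positions,
        resting_segment=session.resting_segment, subject=session.subject,
    )


def sliding_windows(epoch_samples: int, rate: float, width_ms: float = 500.0,
                    overlap_ms: float = 375.0) -> list[tuple[int, int]]:
    """Start/stop sample ranges of sliding windows inside an epoch.

    Windows of ``width_ms`` advance by ``width_ms - overlap_ms`` while they
    fit entirely inside the epoch; count = floor((epoch - width)/step) + 1.
    """
    width = int(round(width_ms * rate / 1000.0))
    overlap = int(round(overlap_ms * rate / 1000.0))
    if width <= overlap:
        raise ValueError("window width must exceed the overlap")
    if width <= 0:
        raise ValueError("window width must be positive")
    if epoch_samples < width:
        raise ValueError(
            f"epoch of {epoch_samples} samples shorter than window ({width})"
        )
    step = width - overlap
    return [
        (ofs, ofs + width) for ofs in range(0, epoch_samples - width + 1, step)
    ]


def _integrate_band(freqs: np.ndarray, psd: np.ndarray,
                    band: tuple[float, float], average: bool) -> np.ndarray:
    """Trapezoid integral of a PSD over ``band`` along the last axis."""
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band} spans fewer than two frequency bins")
    out = np.trapezoid(psd[..., mask], freqs[mask], axis=-1)
    if average:
        out = out / (hi - lo)
    return out


def band_power(window_signal: np.ndarray, rate: float,
               band: tuple[float, float], *, average: bool = False,
               window: str = "hann") -> float | np.ndarray:
    """Band-integrated periodogram power of one window.

    A Hann-tapered periodogram of ``window_signal`` is integrated over
    ``band`` (Hz) with the trapezoid rule; with ``average=True`` the
    integral is divided by the band width. Units uV^2 (uV^2/Hz when
    averaged). Works on the last axis of batched input.
    """
    x = np.asarray(window_signal, float)
    if x.shape[-1] == 0:
        raise ValueError("empty window")
    lo, hi = band
    if lo < 0 or hi > rate / 2 or lo >= hi:
        raise ValueError(f"band {band} not within [0, {rate / 2}] Hz")
    freqs, psd = signal.periodogram(x, fs=rate, window=window,
                                    detrend=False, axis=-1)
    out = _integrate_band(freqs, psd, band, average)
    return float(out) if out.ndim == 0 else out


@dataclass
class FeatureMatrix:
    """Trials x features matrix with per-column provenance.

    provenance columns: ``electrode`` (channel name or component id) and
    ``window`` (window index, or -1 for PCA components). ``trial_index``
    carries one row per feature row (subject, trial_id, grasp).
    """

    X: np.ndarray
    provenance: pd.DataFrame
    band: tuple[float, float]
    trial_index: pd.DataFrame
    reducer_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        if self.X.shape[1] != len(self.provenance):
            raise ValueError("provenance length does not match feature count")
        if self.X.shape[0] != len(self.trial_index):
            raise ValueError("trial_index length does not match row count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def epoch_window_psds(
    session: EEGSession, cfg: FeatureConfig
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-window periodogram PSDs for every retained trial.

    Returns ``(freqs, psds, trial_index)`` with ``psds`` shaped
    [trials x windows x channels x freqs]; excluded trials are skipped.
    Band integration over these PSDs is what :func:`extract_features`
    reports, so any band can be derived from one PSD pass.
    """
    rate = session.rate
    epoch = int(round(cfg.epoch_s * rate))
    wins = sliding_windows(epoch, rate, cfg.width_ms, cfg.overlap_ms)
    width = wins[0][1] - wins[0][0]
    step = wins[1][0] - wins[0][0] if len(wins) > 1 else width

    events = session.events
    keep = ~events["excluded"].to_numpy(bool)
    onsets = np.round(events["cue_on_s"].to_numpy(float)[keep] * rate).astype(int)
    bad = (onsets < 0) | (onsets + epoch > session.n_samples)
    if np.any(bad):
        ids = events["trial_id"].to_numpy()[keep][bad].tolist()
        raise ValueError(f"epoch out of recording range for trials {ids}")

    # [trials x epoch x channels] -> strided windows [trials x n_win x width x ch]
    epochs = np.stack([session.data[o:o + epoch] for o in onsets])
    sw = sliding_window_view(epochs, width, axis=1)  # [tr, epoch-width+1, ch, width]
    sw = sw[:, ::step][:, : len(wins)]               # [tr, n_win, ch, width]
    freqs, psds = signal.periodogram(sw, fs=rate, window="hann",
                                     detrend=False, axis=-1)
    trial_index = pd.DataFrame(
        {
            "subject": session.subject or "sub",
            "trial_id": events["trial_id"].to_numpy()[keep],
            "grasp": events["grasp"].to_numpy()[keep],
        }
    )
    return freqs, psds, trial_index


def extract_features(
    session: EEGSession,
    cfg: FeatureConfig | None = None,
    band: tuple[float, float] | None = None,
    psds: tuple[np.ndarray, np.ndarray, pd.DataFrame] | None = None,
) -> FeatureMatrix:
    """Per-electrode windowed band-power feature matrix for one session.

    With the default configuration each retained trial yields 13 features
    per electrode (p = 32 x 13 = 416). Column order is electrode-major:
    all windows of electrode 0, then electrode 1, ...

    ``psds`` may carry a precomputed :func:`epoch_window_psds` result so
    that several bands can be extracted from a single spectral pass.
    """
    cfg = cfg or FeatureConfig()
    band = band or cfg.band
    freqs, P, trial_index = psds if psds is not None else epoch_window_psds(session, cfg)
    feats = _integrate_band(freqs, P, band, cfg.average)  # [tr, win, ch]
    if cfg.log:
        feats = np.log10(np.maximum(feats, 1e-12))
    n_tr, n_win, n_ch = feats.shape
    X = feats.transpose(0, 2, 1).reshape(n_tr, n_ch * n_win)
    provenance = pd.DataFrame(
        {
            "electrode": np.repeat(list(session.channel_names), n_win),
            "window": np.tile(np.arange(n_win), n_ch),
        }
    )
    return FeatureMatrix(X=X, provenance=provenance, band=band,
                         trial_index=trial_index.reset_index(drop=True))


@dataclass
class FeatureReducer:
    """PCA across the pooled electrode-window features.

    rule : float in (0, 1) -> smallest component count whose cumulative
    explained-variance fraction reaches the rule; int -> fixed count.
    Fitting records the training trial identity so the pipeline can verify
    that no test rows leaked into the fit.
    """

    rule: float | int = 0.9
    mean_: Optional[np.ndarray] = None
    components_: Optional[np.ndarray] = None
    explained_variance_ratio_: Optional[np.ndarray] = None
    fit_rows_: Optional[pd.DataFrame] = None
    reducer_id: str = field(default_factory=lambda: uuid.uuid4().hex)

    @property
    def is_fitted(self) -> bool:
        return self.components_ is not None

    @property
    def n_components(self) -> int:
        if not self.is_fitted:
            raise NotFittedError("reducer has not been fitted")
        return self.components_.shape[0]

    def fit(self, features: FeatureMatrix) -> "FeatureReducer":
        from sklearn.decomposition import PCA

        X = features.X
        if isinstance(self.rule, float):
            if not 0 < self.rule < 1:
                raise ValueError("variance rule must lie in (0, 1)")
            pca = PCA(n_components=None, svd_solver="full").fit(X)
            cum = np.cumsum(pca.explained_variance_ratio_)
            k = int(np.searchsorted(cum, self.rule - 1e-12) + 1)
        else:
            k = int(self.rule)
            if k < 1 or k > min(X.shape):
                raise ValueError(f"component count {k} out of range")
            pca = PCA(n_components=None, svd_solver="full").fit(X)
        self.mean_ = pca.mean_
        self.components_ = pca.components_[:k]
        self.explained_variance_ratio_ = pca.explained_variance_ratio_[:k]
        self.fit_rows_ = features.trial_index.copy()
        return self

    def transform(self, features: FeatureMatrix) -> FeatureMatrix:
        if not self.is_fitted:
            raise NotFittedError("reducer has not been fitted")
        Z = (features.X - self.mean_) @ self.components_.T
        provenance = pd.DataFrame(
            {"electrode": [f"PC{i + 1}" for i in range(Z.shape[1])],
             "window": -1}
        )
        return FeatureMatrix(X=Z, provenance=provenance, band=features.band,
                             trial_index=features.trial_index,
                             reducer_id=self.reducer_id)

    def assert_fitted_on(self, train_index: pd.DataFrame) -> None:
        """Raise :class:`LeakageError` unless fitted exactly on ``train_index``."""
        if not self.is_fitted:
            raise NotFittedError("reducer has not been fitted")
        a = self.fit_rows_[["subject", "trial_id"]].reset_index(drop=True)
        b = train_index[["subject", "trial_id"]].reset_index(drop=True)
        if len(a) != len(b) or not a.equals(b):
            raise LeakageError(
                "reducer was fitted on rows other than the training fold"
            )


def concat_features(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-subject feature matrices that share provenance and band."""
    first = parts[0]
    for p in parts[1:]:
        if p.band != first.band or not p.provenance.equals(first.provenance):
            raise ValueError("feature matrices have mismatched provenance")
    return FeatureMatrix(
        X=np.vstack([p.X for p in parts]),
        provenance=first.provenance,
        band=first.band,
        trial_index=pd.concat([p.trial_index for p in parts],
                              ignore_index=True),
        reducer_id=first.reducer_id,
    )
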