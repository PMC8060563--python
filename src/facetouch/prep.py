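"""Preprocessing: onset trimming, feature selection, windowing, time-shift
augmentation, FFT stacking, and train-statistics standardization.

The stages mirror the preparation of the wrist-IMU classification pipeline:

1.  Detect movement onset (gyro-magnitude threshold over a static baseline)
    and anchor a fixed window of the FIRST ``window_ms`` of movement --
    prediction-before-touch requires the earliest part of the gesture.
2.  Keep 7 of the 9 channels (accel x/y/z, gyro x/y/z, pitch); roll and yaw
    carry no discriminative pattern for this task and are dropped.
3.  Drop gestures shorter than the window; augment training gestures by
    sliding the window forward in time.
4.  Stack per-channel FFT magnitudes onto the raw channels for a depth of 14.
5.  Standardize each channel to zero mean / unit SD using TRAINING statistics
    only; the same statistics transform the test set (no leakage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulate import SAMPLE_RATE_HZ, TrialRecording

logger = logging.getLogger(__name__)

RAW_FEATURES = ("ax", "ay", "az", "gx", "gy", "gz", "pitch")
FEATURE_NAMES = RAW_FEATURES + tuple(f"fft_{c}" for c in RAW_FEATURES)
_GYRO_COLS = slice(3, 6)
_RAW_COLS = [0, 1, 2, 3, 4, 5, 6]  # drop roll (7) and yaw (8)

LABEL_TO_INT = {"no_touch": 0, "face_touch": 1}


@dataclass
class FeatureTensor:
    """Stacked windows ready for the classifier.

    ``data`` has shape (n_windows, W, 14): channels 0-6 are raw accel x/y/z,
    gyro x/y/z, pitch; channels 7-13 the FFT magnitudes of channels 0-6.
    ``labels`` is binary (1 = face touch) and aligned 1:1 with windows.
    """

    data: np.ndarray
    labels: np.ndarray
    participant_ids: np.ndarray
    window_ms: float
    stats: dict | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[2] != len(FEATURE_NAMES):
            raise ValueError(
                f"data must be n x W x {len(FEATURE_NAMES)}, got {self.data.shape}"
            )
        if len(self.labels) != len(self.data) or len(self.participant_ids) != len(self.data):
            raise ValueError("labels/participant_ids must align 1:1 with windows")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]


def window_samples(window_ms: float, sample_rate_hz: float = SAMPLE_RATE_HZ) -> int:
    """Window length in samples: round(window_ms * fs / 1000)."""
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    return int(round(window_ms * sample_rate_hz / 1000.0))


def detect_onset(
    trial: TrialRecording,
    k_sd: float = 4.0,
    sustain: int = 5,
    baseline_ms: float = 200.0,
) -> int:
    """Movement onset: first index where the gyro magnitude exceeds
    baseline mean + ``k_sd`` x baseline SD for ``sustain`` consecutive
    samples.  Returns 0 (with a warning) if the threshold is never
    sustained -- e.g. a recording with no movement.
    """
    n_base = int(round(baseline_ms * trial.sample_rate_hz / 1000.0))
    if trial.n_samples <= n_base:
        raise ValueError(
            f"trial shorter ({trial.n_samples} samples) than the "
            f"{baseline_ms} ms baseline window ({n_base} samples)"
        )
    mag = np.linalg.norm(trial.channels[:, _GYRO_COLS], axis=1)
    thr = mag[:n_base].mean() + k_sd * mag[:n_base].std()
    above = mag > thr
    if sustain > 1:
        kernel = np.ones(sustain, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == sustain
        idx = np.flatnonzero(runs)
    else:
        idx = np.flatnonzero(above)
    if idx.size == 0:
        warnings.warn(
            f"no sustained movement above threshold in trial "
            f"{trial.trial_id or '<unnamed>'}; onset set to 0",
            stacklevel=2,
        )
        return 0
    return int(idx[0])


def select_features(trial: TrialRecording) -> np.ndarray:
    """Return the T x 7 feature matrix (accel x/y/z, gyro x/y/z, pitch)."""
    return trial.channels[:, _RAW_COLS]


def _onset_of(trial: TrialRecording, policy: str, **onset_kwargs) -> int:
    if policy == "detect":
        return detect_onset(trial, **onset_kwargs)
    if policy == "true":
        if trial.true_onset_sample is None:
            raise ValueError(
                f"trial {trial.trial_id!r} has no ground-truth onset; "
                "use onset_policy='detect'"
            )
        return trial.true_onset_sample
    raise ValueError(f"unknown onset policy {policy!r}")


def window_trials(
    trials: Sequence[TrialRecording],
    window_ms: float,
    onset_policy: str = "detect",
    **onset_kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Extract the first ``window_ms`` of movement from each trial.

    Trials with fewer than W post-onset samples are dropped and counted.
    Returns ``(windows (n, W, 7), labels, participant_ids, report)``.
    """
    w = window_samples(window_ms)
    kept, labels, pids = [], [], []
    dropped = 0
    for trial in trials:
        onset = _onset_of(trial, onset_policy, **onset_kwargs)
        feats = select_features(trial)
        if feats.shape[0] - onset >= w:
            kept.append(feats[onset : onset + w])
            labels.append(LABEL_TO_INT[trial.label])
            pids.append(trial.participant_id)
        else:
            dropped += 1
    report = {"kept": len(kept), "dropped": dropped, "window_samples": w}
    if dropped:
        logger.info("window_trials: dropped %d/%d short gestures", dropped, len(trials))
    data = np.stack(kept) if kept else np.empty((0, w, len(RAW_FEATURES)))
    return data, np.asarray(labels, dtype=int), np.asarray(pids, dtype=object), report


def augment(
    trials: Sequence[TrialRecording],
    window_ms: float,
    n_shifts: int = 10,
    shift_step: int = 1,
    partition: str = "train",
    onset_policy: str = "detect",
    **onset_kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Time-shift augmentation: for each kept trial emit the onset-anchored
    window plus up to ``n_shifts`` extra windows starting at
    ``onset + i * shift_step`` (i = 1..n_shifts), each only when enough
    samples remain.  Labels are copied to every shifted window.

    Augmentation enlarges the TRAINING set only; calling it on any other
    partition is a leakage bug and raises.
    """
    if partition != "train":
        raise ValueError(
            "time-shift augmentation must only be applied to the training "
            f"partition, got partition={partition!r}"
        )
    if n_shifts < 0:
        raise ValueError("n_shifts must be >= 0")
    if shift_step < 1:
        raise ValueError("shift_step must be >= 1")
    w = window_samples(window_ms)
    kept, labels, pids = [], [], []
    dropped = 0
    for trial in trials:
        onset = _onset_of(trial, onset_policy, **onset_kwargs)
        feats = select_features(trial)
        avail = feats.shape[0] - onset
        if avail < w:
            dropped += 1
            continue
        max_shift = min(n_shifts, (avail - w) // shift_step)
        for i in range(max_shift + 1):
            start = onset + i * shift_step
            kept.append(feats[start : start + w])
            labels.append(LABEL_TO_INT[trial.label])
            pids.append(trial.participant_id)
    report = {"kept": len(kept), "dropped": dropped, "window_samples": w}
    data = np.stack(kept) if kept else np.empty((0, w, len(RAW_FEATURES)))
    return data, np.asarray(labels, dtype=int), np.asarray(pids, dtype=object), report


def fft_stack(windows: np.ndarray) -> np.ndarray:
    """Stack per-channel DFT magnitudes onto raw windows: (n, W, 7) ->
    (n, W, 14).  Bin order is 0..W-1 so raw and spectral stacks share the
    time/bin axis."""
    windows = np.asarray(windows)
    if windows.ndim != 3 or windows.shape[2] != len(RAW_FEATURES):
        raise ValueError(f"expected (n, W, 7) windows, got {windows.shape}")
    bad = ~np.isfinite(windows).all(axis=(1, 2))
    if bad.any():
        raise ValueError(
            f"non-finite values in window(s) {np.flatnonzero(bad).tolist()[:10]}"
        )
    spectra = np.abs(np.fft.fft(windows, axis=1))
    return np.concatenate([windows, spectra], axis=2)


class ChannelStandardizer:
    """Per-channel zero-mean / unit-SD scaler for (n, W, C) tensors.

    Statistics are pooled over windows and time steps ("across each
    feature"); fit on training data only, then applied unchanged to the test
    set so no test-set information enters the transform.
    Follows the scikit-learn fit/transform protocol.
    """

    def __init__(self, sd_floor: float = 1e-12):
        self.sd_floor = sd_floor

    def fit(self, X: np.ndarray, y=None) -> "ChannelStandardizer":
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[0] == 0:
            raise ValueError("fit requires a non-empty (n, W, C) tensor")
        self.mean_ = X.mean(axis=(0, 1))
        sd = X.std(axis=(0, 1))
        if np.any(sd < self.sd_floor):
            warnings.warn(
                f"zero-variance channel(s) {np.flatnonzero(sd < self.sd_floor).tolist()}; "
                f"SD floored at {self.sd_floor}",
                stacklevel=2,
            )
        self.scale_ = np.maximum(sd, self.sd_floor)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"sd_floor": self.sd_floor}

    def set_params(self, **params) -> "ChannelStandardizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @property
    def stats(self) -> dict:
        return {"mean": self.mean_.tolist(), "sd": self.scale_.tolist()}


def standardize(
    train: FeatureTensor, test: FeatureTensor | None = None
) -> tuple[FeatureTensor, FeatureTensor | None, dict]:
    """Standardize a train (and optionally test) tensor with TRAINING stats.

    Returns new tensors plus the per-channel statistics for deployment.
    """
    scaler = ChannelStandardizer().fit(train.data)
    train_std = FeatureTensor(
        scaler.transform(train.data),
        train.labels,
        train.participant_ids,
        train.window_ms,
        stats=scaler.stats,
        report=train.report,
    )
    test_std = None
    if test is not None:
        test_std = FeatureTensor(
            scaler.transform(test.data),
            test.labels,
            test.participant_ids,
            test.window_ms,
            stats=scaler.stats,
            report=test.report,
        )
    return train_std, test_std, scaler.stats


def prepare_tensors(
    train_trials: Sequence[TrialRecording],
    test_trials: Sequence[TrialRecording],
    window_ms: float,
    n_shifts: int = 10,
    shift_step: int = 1,
    onset_policy: str = "detect",
    **onset_kwargs,
) -> tuple[FeatureTensor, FeatureTensor, dict]:
    """End-to-end preparation of standardized train/test feature tensors.

    Training trials are augmented by time shifting; test trials contribute
    exactly one onset-anchored window each (no augmentation).
    """
    xw, yl, pid, rep = augment(
        train_trials,
        window_ms,
        n_shifts=n_shifts,
        shift_step=shift_step,
        partition="train",
        onset_policy=onset_policy,
        **onset_kwargs,
    )
    train = FeatureTensor(fft_stack(xw), yl, pid, window_ms, report=rep)
    xw_t, yl_t, pid_t, rep_t = window_trials(
        test_trials, window_ms, onset_policy=onset_policy, **onset_kwargs
    )
    test = FeatureTensor(fft_stack(xw_t), yl_t, pid_t, window_ms, report=rep_t)
    train_std, test_std, stats = standardize(train, test)
    return train_std, test_std, stats
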