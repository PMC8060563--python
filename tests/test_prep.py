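"""Preprocessing tests: onset detection, feature selection, windowing,
augmentation accounting, the FFT stack against a brute-force DFT, and
train-statistics standardization."""

import numpy as np
import pytest

from facetouch import prep
from facetouch.prep import (
    ChannelStandardizer,
    FeatureTensor,
    augment,
    detect_onset,
    fft_stack,
    select_features,
    standardize,
    window_samples,
    window_trials,
)
from facetouch.simulate import (
    SAMPLE_RATE_HZ,
    GestureParams,
    TrialRecording,
    simulate_trial,
)

NOISELESS = dict(noise_sd_accel=0.0, noise_sd_gyro=0.0, noise_sd_euler=0.0)


def _trial_from_channels(channels, label="face_touch", pid="P001", onset=None):
    return TrialRecording(
        participant_id=pid, run=1, stance="sitting", label=label,
        sample_rate_hz=SAMPLE_RATE_HZ, channels=channels,
        true_onset_sample=onset, trial_id="t0",
    )


# -- onset detection --------------------------------------------------------


@pytest.mark.parametrize("stance", ["sitting", "standing", "walking"])
def test_onset_zero_noise_near_ground_truth(stance):
    """Noise-free trial with ground-truth onset at sample 45: the detector
    lands within [42, 48]."""
    rec = simulate_trial(
        GestureParams(stance=stance, static_delay_s=45 / SAMPLE_RATE_HZ, seed=8, **NOISELESS)
    )
    assert rec.true_onset_sample == 45
    assert 42 <= detect_onset(rec) <= 48


def test_onset_constant_trial_warns_and_returns_zero():
    channels = np.tile([0, 0, 1, 0, 0, 0, 0, 0, 0.0], (120, 1))
    with pytest.warns(UserWarning, match="onset set to 0"):
        assert detect_onset(_trial_from_channels(channels)) == 0


def test_onset_trial_shorter_than_baseline_errors():
    channels = np.zeros((10, 9))
    with pytest.raises(ValueError, match="baseline"):
        detect_onset(_trial_from_channels(channels))


# -- feature selection ------------------------------------------------------


def test_select_features_depth_and_order():
    """9 channels minus roll and yaw leaves depth 7, in canonical order."""
    channels = np.arange(9 * 5, dtype=float).reshape(5, 9)
    out = select_features(_trial_from_channels(channels))
    assert out.shape == (5, 7)
    np.testing.assert_array_equal(out, channels[:, [0, 1, 2, 3, 4, 5, 6]])


def test_select_features_ignores_roll_yaw():
    rng = np.random.default_rng(0)
    channels = rng.normal(size=(50, 9))
    base = select_features(_trial_from_channels(channels.copy()))
    channels[:, 7:9] = np.nan  # poison the dropped channels only
    out = select_features(_trial_from_channels(channels))
    assert np.isfinite(out).all()
    np.testing.assert_array_equal(out, base)


# -- windowing and augmentation --------------------------------------------


def test_window_samples_at_550ms():
    assert window_samples(550.0) == 50
    assert window_samples(440.0) == 40
    assert window_samples(990.0) == 90
    with pytest.raises(ValueError):
        window_samples(0.0)


def _movement_trial(n_post_onset, onset=20, label="face_touch", pid="P001"):
    rng = np.random.default_rng(42)
    channels = rng.normal(size=(onset + n_post_onset, 9))
    return _trial_from_channels(channels, label=label, pid=pid, onset=onset)


def test_window_boundary_inclusive_exclusive():
    """A trial with exactly W post-onset samples is kept; W-1 is dropped and
    counted."""
    w = window_samples(550.0)
    keep = _movement_trial(w)
    drop = _movement_trial(w - 1)
    data, labels, pids, report = window_trials([keep, drop], 550.0, onset_policy="true")
    assert data.shape == (1, w, 7)
    assert report == {"kept": 1, "dropped": 1, "window_samples": w}


def test_augment_zero_shifts_is_identity():
    trials = [_movement_trial(60), _movement_trial(55)]
    base = window_trials(trials, 550.0, onset_policy="true")
    aug = augment(trials, 550.0, n_shifts=0, onset_policy="true")
    np.testing.assert_array_equal(base[0], aug[0])
    np.testing.assert_array_equal(base[1], aug[1])


def test_augment_count_formula():
    """One trial with >= W + N*step post-onset samples yields N+1 windows;
    scarcer trials yield 1 + floor((avail - W)/step)."""
    w = window_samples(550.0)
    rich = _movement_trial(w + 10)
    data, labels, pids, _ = augment([rich], 550.0, n_shifts=10, shift_step=1, onset_policy="true")
    assert data.shape[0] == 11
    assert set(labels) == {1} and set(pids) == {"P001"}

    scarce = _movement_trial(w + 7)
    data, *_ = augment([scarce], 550.0, n_shifts=10, shift_step=2, onset_policy="true")
    assert data.shape[0] == 1 + 3  # floor(7 / 2) feasible shifts


def test_augment_windows_are_shifted_views():
    w = window_samples(550.0)
    trial = _movement_trial(w + 3)
    data, *_ = augment([trial], 550.0, n_shifts=3, shift_step=1, onset_policy="true")
    feats = select_features(trial)
    for i in range(4):
        np.testing.assert_array_equal(data[i], feats[20 + i : 20 + i + w])


def test_augment_refuses_test_partition():
    with pytest.raises(ValueError, match="training"):
        augment([_movement_trial(60)], 550.0, partition="test", onset_policy="true")


def test_augment_negative_shifts_error():
    with pytest.raises(ValueError):
        augment([_movement_trial(60)], 550.0, n_shifts=-1, onset_policy="true")


# -- FFT stack --------------------------------------------------------------


def test_fft_constant_window_dc_only():
    w = 16
    c = 2.5
    windows = np.full((1, w, 7), c)
    out = fft_stack(windows)
    assert out.shape == (1, w, 14)
    np.testing.assert_allclose(out[0, 0, 7:], w * abs(c), atol=1e-9)
    np.testing.assert_allclose(out[0, 1:, 7:], 0.0, atol=1e-9)


def test_fft_matches_naive_dft():
    """Spectral channels equal a brute-force O(W^2) DFT magnitude."""
    rng = np.random.default_rng(7)
    w = 16
    windows = rng.normal(size=(3, w, 7))
    out = fft_stack(windows)
    k = np.arange(w)
    dft = np.exp(-2j * np.pi * np.outer(k, k) / w)  # naive DFT matrix
    for n in range(3):
        for c in range(7):
            naive = np.abs(dft @ windows[n, :, c])
            np.testing.assert_allclose(out[n, :, 7 + c], naive, atol=1e-9)


def test_fft_depth_is_14(tiny_dataset):
    trials, _ = tiny_dataset
    data, *_ = window_trials(trials[:6], 440.0, onset_policy="true")
    assert fft_stack(data).shape[2] == 14


def test_fft_nan_input_names_window():
    windows = np.zeros((3, 8, 7))
    windows[1, 2, 3] = np.nan
    with pytest.raises(ValueError, match=r"\[1\]"):
        fft_stack(windows)


# -- standardization --------------------------------------------------------


def _tensor(data, pid="A"):
    n = data.shape[0]
    return FeatureTensor(
        data, np.zeros(n, dtype=int), np.array([pid] * n, dtype=object), 550.0
    )


def test_standardize_train_definition():
    rng = np.random.default_rng(1)
    data = rng.normal(3.0, 5.0, (40, 20, 14))
    train, _, stats = standardize(_tensor(data))
    assert np.abs(train.data.mean(axis=(0, 1))).max() < 1e-8
    assert np.abs(train.data.std(axis=(0, 1)) - 1.0).max() < 1e-6
    assert len(stats["mean"]) == 14


def test_standardize_is_idempotent():
    rng = np.random.default_rng(2)
    data = rng.normal(-1.0, 2.0, (30, 10, 14))
    once, _, _ = standardize(_tensor(data))
    twice, _, _ = standardize(once)
    np.testing.assert_allclose(twice.data, once.data, atol=1e-9)


def test_test_set_uses_train_statistics_only():
    """The test tensor is shifted by the *training* stats, so its own means
    stay non-zero: no leakage of test-set statistics."""
    rng = np.random.default_rng(3)
    train = _tensor(rng.normal(0.0, 1.0, (50, 12, 14)))
    test = _tensor(rng.normal(4.0, 1.0, (50, 12, 14)), pid="B")
    train_std, test_std, stats = standardize(train, test)
    expected = (test.data - np.array(stats["mean"])) / np.array(stats["sd"])
    np.testing.assert_allclose(test_std.data, expected)
    assert np.abs(test_std.data.mean(axis=(0, 1))).min() > 1.0


def test_zero_variance_channel_floored_with_warning():
    data = np.random.default_rng(4).normal(size=(10, 6, 14))
    data[..., 5] = 7.0
    with pytest.warns(UserWarning, match="zero-variance"):
        scaler = ChannelStandardizer().fit(data)
    out = scaler.transform(data)
    assert np.isfinite(out).all()


def test_prepare_tensors_end_to_end(tiny_dataset):
    trials, manifest = tiny_dataset
    pids = sorted(manifest["participant_id"].unique())
    train_tr = [t for t in trials if t.participant_id in pids[:3]]
    test_tr = [t for t in trials if t.participant_id in pids[3:]]
    train, test, stats = prep.prepare_tensors(train_tr, test_tr, 440.0, n_shifts=2)
    assert train.data.shape[1:] == (40, 14)
    assert test.data.shape[1:] == (40, 14)
    assert set(train.participant_ids).isdisjoint(test.participant_ids)
    # augmented training windows: between 1x and 3x the kept trial count
    assert train.n_windows >= train.report["kept"] > 0
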