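"""Simulator unit and property tests: kinematic consistency, protocol
counts, determinism, and the psychophysics session generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from facetouch import simulate as sim
from facetouch.simulate import (
    G0,
    SAMPLE_RATE_HZ,
    GestureParams,
    PsychSessionParams,
    simulate_trial,
    simulate_dataset,
    simulate_psych_session,
)

NOISELESS = dict(noise_sd_accel=0.0, noise_sd_gyro=0.0, noise_sd_euler=0.0)


def test_degenerate_reach_is_static():
    """A zero-displacement, zero-rotation 'reach' leaves only gravity: all
    gyro channels identically 0 and accelerometer constant at the gravity
    projection."""
    p = GestureParams(
        label="no_touch", stance="sitting", static_delay_s=0.3,
        movement_duration_s=0.4,
        start_pos=np.zeros(3), start_euler=np.zeros(3),
        target_pos=np.zeros(3), target_euler=np.zeros(3),
        seed=1, **NOISELESS,
    )
    rec = simulate_trial(p)
    assert np.all(rec.channels[:, 3:6] == 0.0)
    np.testing.assert_allclose(rec.channels[:, 0:2], 0.0, atol=1e-12)
    np.testing.assert_allclose(rec.channels[:, 2], 1.0, atol=1e-12)


def _double_integrate_piecewise(t, a, breaks):
    """Spline double integration split at known kink indices; exact for the
    piecewise-polynomial minimum-jerk acceleration."""
    pts = sorted({0, len(t) - 1, *breaks})
    v = np.zeros_like(a)
    x = np.zeros_like(a)
    v0 = np.zeros(a.shape[1])
    x0 = np.zeros(a.shape[1])
    for i0, i1 in zip(pts[:-1], pts[1:]):
        seg = slice(i0, i1 + 1)
        vi = v0 + CubicSpline(t[seg], a[seg], axis=0).antiderivative()(t[seg])
        xi = x0 + CubicSpline(t[seg], vi, axis=0).antiderivative()(t[seg])
        v[seg], x[seg] = vi, xi
        v0, x0 = vi[-1], xi[-1]
    return v, x


@pytest.mark.parametrize("label", ["face_touch", "no_touch"])
def test_physics_oracle_min_jerk_recovery(label):
    """With zero noise, rotating the accelerometer back to the world frame,
    removing gravity, and double-integrating reproduces the closed-form
    minimum-jerk displacement profile to 1e-6 relative error."""
    fs = SAMPLE_RATE_HZ
    duration = 110 / fs  # movement start/end on the sample grid
    p = GestureParams(
        label=label, stance="sitting", static_delay_s=0.5,
        movement_duration_s=duration, seed=3, **NOISELESS,
    )
    rec = simulate_trial(p)
    t = np.arange(rec.n_samples) / fs
    yaw, pitch, roll = rec.channels[:, 8], rec.channels[:, 6], rec.channels[:, 7]
    rot = Rotation.from_euler("ZYX", np.column_stack([yaw, pitch, roll]), degrees=True)
    a_world = rot.apply(rec.channels[:, :3] * G0) - np.array([0.0, 0.0, G0])
    n0 = rec.true_onset_sample
    _, x = _double_integrate_piecewise(t, a_world, [n0, n0 + 110])
    tau = np.clip((t - n0 / fs) / duration, 0.0, 1.0)
    s, _, _ = sim.minimum_jerk(tau)
    dp = x[-1]
    rel_err = np.abs(x - np.outer(s, dp)).max() / np.linalg.norm(dp)
    assert rel_err < 1e-6


def test_movement_duration_mean():
    """1,000 duration draws average ~1.2 s (the time a hand needs to reach
    and touch the face)."""
    rng = np.random.default_rng(123)
    draws = [sim.draw_movement_duration(rng) for _ in range(1000)]
    assert abs(np.mean(draws) - 1.2) < 0.02


@pytest.mark.parametrize(
    "bad",
    [
        dict(movement_duration_s=0.0),
        dict(movement_duration_s=-1.0),
        dict(stance="flying"),
        dict(label="maybe_touch"),
        dict(static_delay_s=-0.1),
        dict(noise_sd_gyro=-1.0),
    ],
)
def test_invalid_params_rejected(bad):
    with pytest.raises(ValueError):
        simulate_trial(GestureParams(**bad))


def test_dataset_protocol_counts_single_participant():
    """Default protocol: 2 runs x 3 stances x (10 + 10) = 120 trials per
    participant, exactly balanced 60/60 by label and 40 per stance."""
    trials, manifest = simulate_dataset(1, seed=0)
    assert len(trials) == 120 and len(manifest) == 120
    assert manifest["label"].value_counts().to_dict() == {
        "face_touch": 60, "no_touch": 60,
    }
    assert set(manifest["stance"].value_counts()) == {40}


def test_dataset_empty():
    trials, manifest = simulate_dataset(0)
    assert trials == [] and len(manifest) == 0


def test_per_participant_label_balance(tiny_dataset):
    _, manifest = tiny_dataset
    balance = manifest.groupby("participant_id")["label"].value_counts().unstack()
    assert (balance["face_touch"] == balance["no_touch"]).all()


def test_dataset_deterministic_given_seed():
    a, ma = simulate_dataset(2, trials_per_condition=1, seed=99)
    b, mb = simulate_dataset(2, trials_per_condition=1, seed=99)
    assert ma.equals(mb)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.channels, rb.channels)
    c, _ = simulate_dataset(2, trials_per_condition=1, seed=100)
    assert not np.array_equal(a[0].channels, c[0].channels)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(delay=st.floats(min_value=0.0, max_value=1.5))
def test_true_onset_matches_static_delay(delay):
    """Ground-truth onset is always round(static_delay * sample_rate)."""
    rec = simulate_trial(GestureParams(static_delay_s=delay, movement_duration_s=0.7, seed=5))
    assert rec.true_onset_sample == int(round(delay * SAMPLE_RATE_HZ))


# -- psychophysics sessions -------------------------------------------------


def test_psych_session_counts():
    """100-trial default session: 70 no-feedback, 10 per modality."""
    sess = simulate_psych_session(PsychSessionParams(seed=1))
    counts = {m: sum(t.modality == m for t in sess) for m in ("vibrotactile", "auditory", "visual", "none")}
    assert counts == {"vibrotactile": 10, "auditory": 10, "visual": 10, "none": 70}
    assert all(not t.success_true for t in sess if t.modality == "none")


def test_psych_counts_largest_remainder_warns():
    with pytest.warns(UserWarning, match="not divisible"):
        counts = sim.feedback_counts(100, 0.31)
    assert sum(counts.values()) == 31
    assert sorted(counts.values()) == [10, 10, 11]


def test_psych_degenerate_rt_extraction():
    """With the response-time SD collapsed to ~0, every extracted
    vibrotactile response time equals the 427.3 ms mean to within one
    sample period."""
    from facetouch.psych import extract_response_time

    params = PsychSessionParams(
        seed=2, rt_sd_ms={m: 1e-9 for m in sim.MODALITIES}
    )
    period_ms = 1000.0 / SAMPLE_RATE_HZ
    for trial in simulate_psych_session(params):
        if trial.modality != "vibrotactile":
            continue
        rt = extract_response_time(trial)
        assert rt is not None
        assert abs(rt - 427.3) <= period_ms


def test_psych_rt_draw_mean():
    """Across many sessions the generator's vibrotactile response-time draws
    average 427.3 ms (within 3 ms)."""
    draws = []
    for rep in range(1000):
        sess = simulate_psych_session(
            PsychSessionParams(n_trials=30, feedback_fraction=1.0, seed=rep)
        )
        draws += [t.rt_true_ms for t in sess if t.modality == "vibrotactile"]
    assert len(draws) == 10_000
    assert abs(np.mean(draws) - 427.3) < 3.0
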