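"""Synthetic wrist-IMU gesture recordings and psychophysics sessions.

The generator emulates the data-collection protocol behind the face-touch
prediction pipeline: participants wearing a wrist IMU (3-axis accelerometer,
3-axis gyroscope, on-device pitch/roll/yaw) perform balanced face-touch and
non-touch reaches while sitting, standing, or walking.  Each trial starts with
a static rest segment of variable length, followed by a smooth point-to-point
reach modeled as a minimum-jerk trajectory (the standard motor-control model
for unconstrained reaching), superimposed on a stance-dependent baseline.

Movement onset additionally carries a brief, exponentially decaying rotation
transient that models the contact-release jolt of lifting the hand off a
resting surface; real IMU recordings of table-started reaches show such a
transient, and it is what makes sample-accurate onset detection physically
possible (an ideal minimum-jerk profile has zero initial velocity and
acceleration).

All channels are mutually consistent: the accelerometer reads the specific
force of the analytic trajectory expressed in the (rotating) sensor frame, the
gyroscope reads the exact body rates of the orientation profile, and the Euler
channels are the ground-truth sensor-frame angles.  With noise disabled the
recordings are exactly integrable back to the analytic trajectory, which the
test-suite uses as a physics oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

G0 = 9.80665  # m/s^2 per g
SAMPLE_RATE_HZ = 90.9  # one sample every 11 ms

LABELS = ("no_touch", "face_touch")
STANCES = ("sitting", "standing", "walking")
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz", "pitch", "roll", "yaw")

# Stance-dependent rest pose: position (m, arbitrary world origin at the
# resting hand) and Euler angles (roll, pitch, yaw in deg; wrist flat).
_START_POSE = {
    "sitting": (np.zeros(3), np.zeros(3)),
    "standing": (np.array([0.0, 0.05, -0.10]), np.array([0.0, -5.0, 0.0])),
    "walking": (np.array([0.0, 0.05, -0.10]), np.array([0.0, -5.0, 0.0])),
}

# Reach endpoints relative to the rest pose: displacement (m) and Euler change
# (roll, pitch, yaw in deg).  Face reaches end at the face; non-touch reaches
# are a mixture of a table/object reach, a sideways reach, and a head-adjacent
# gesture (ear/hair) that shares most of its path with a face touch and only
# diverges late -- the realistic hard negatives of this task.
_FACE_TARGET = {
    "sitting": (np.array([0.05, 0.28, 0.35]), np.array([25.0, -70.0, 15.0])),
    "standing": (np.array([0.05, 0.25, 0.45]), np.array([25.0, -75.0, 15.0])),
    "walking": (np.array([0.05, 0.25, 0.45]), np.array([25.0, -75.0, 15.0])),
}
_NONTOUCH_TARGETS = (
    ("table_reach", np.array([0.35, 0.22, 0.02]), np.array([5.0, -20.0, 25.0]), 0.40),
    ("side_reach", np.array([-0.30, 0.12, 0.08]), np.array([-10.0, -18.0, -30.0]), 0.35),
    ("head_adjacent", np.array([0.16, 0.26, 0.30]), np.array([18.0, -48.0, 8.0]), 0.25),
)

# Walking baseline: gentle vertical bounce at the step cadence plus lateral
# sway and wrist wobble at half cadence (tethered indoor walking with the
# instrumented hand held ready, not free arm swing).
_WALK_POS_AMP_M = np.array([0.003, 0.0, 0.002])      # x lateral, z vertical
_WALK_EULER_AMP_DEG = np.array([0.30, 0.30, 0.15])   # roll, pitch, yaw


@dataclass
class GestureParams:
    """Parameters of a single simulated reach trial."""

    label: str = "face_touch"
    stance: str = "sitting"
    static_delay_s: float = 0.5
    movement_duration_s: float = 1.2
    start_pos: np.ndarray | None = None          # m
    start_euler: np.ndarray | None = None        # roll, pitch, yaw (deg)
    target_pos: np.ndarray | None = None
    target_euler: np.ndarray | None = None
    noise_sd_accel: float = 0.02                 # g
    noise_sd_gyro: float = 1.5                   # deg/s
    noise_sd_euler: float = 0.1                  # deg
    walking_cadence_hz: float = 1.8
    onset_twist_rate_dps: float = 20.0           # contact-release transient
    onset_twist_tau_s: float = 0.12
    hold_s: float = 0.3                          # post-reach hold at target
    sample_rate_hz: float = SAMPLE_RATE_HZ
    seed: int = 0


@dataclass
class TrialRecording:
    """One gesture's multichannel IMU time series plus metadata.

    ``channels`` is a T x 9 matrix ordered accel x/y/z (g), gyro x/y/z
    (deg/s), pitch/roll/yaw (deg).  ``true_onset_sample`` is the simulator's
    ground-truth movement onset (``None`` for real recordings).
    """

    participant_id: str
    run: int
    stance: str
    label: str
    sample_rate_hz: float
    channels: np.ndarray
    true_onset_sample: int | None = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != len(CHANNELS):
            raise ValueError(
                f"channels must be T x {len(CHANNELS)}, got {self.channels.shape}"
            )
        if self.channels.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]


def _validate_params(params: GestureParams) -> None:
    if params.label not in LABELS:
        raise ValueError(f"unknown label {params.label!r}; expected one of {LABELS}")
    if params.stance not in STANCES:
        raise ValueError(f"unknown stance {params.stance!r}; expected one of {STANCES}")
    if not params.movement_duration_s > 0:
        raise ValueError("movement_duration_s must be positive")
    if params.static_delay_s < 0:
        raise ValueError("static_delay_s must be non-negative")
    for name in ("noise_sd_accel", "noise_sd_gyro", "noise_sd_euler"):
        if getattr(params, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    if params.sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")


def minimum_jerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized minimum-jerk profile and its first two derivatives.

    ``tau`` is normalized time in [0, 1]; derivatives are with respect to tau
    (divide by D and D**2 for physical time).
    """
    tau = np.clip(tau, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    d2s = 60 * tau - 180 * tau**2 + 120 * tau**3
    inside = (tau > 0) & (tau < 1)
    ds = np.where(inside, ds, 0.0)
    d2s = np.where(inside, d2s, 0.0)
    return s, ds, d2s


def default_poses(
    label: str, stance: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (start_pos, start_euler, target_pos, target_euler) for a trial."""
    p0, e0 = (a.copy() for a in _START_POSE[stance])
    if label == "face_touch":
        dp, de = _FACE_TARGET[stance]
    else:
        probs = np.array([t[3] for t in _NONTOUCH_TARGETS])
        idx = rng.choice(len(_NONTOUCH_TARGETS), p=probs / probs.sum())
        _, dp, de, _ = _NONTOUCH_TARGETS[idx]
    dp = dp + rng.normal(0.0, 0.01, 3)
    de = de + rng.normal(0.0, 2.0, 3)
    return p0, e0, p0 + dp, e0 + de


def _euler_to_body_rates(euler_deg: np.ndarray, euler_rate_dps: np.ndarray) -> np.ndarray:
    """Exact body angular rates (deg/s) from ZYX Euler angles and their rates."""
    roll = np.deg2rad(euler_deg[:, 0])
    pitch = np.deg2rad(euler_deg[:, 1])
    droll, dpitch, dyaw = (np.deg2rad(euler_rate_dps[:, i]) for i in range(3))
    wx = droll - dyaw * np.sin(pitch)
    wy = dpitch * np.cos(roll) + dyaw * np.cos(pitch) * np.sin(roll)
    wz = -dpitch * np.sin(roll) + dyaw * np.cos(pitch) * np.cos(roll)
    return np.rad2deg(np.column_stack([wx, wy, wz]))


def simulate_trial(params: GestureParams) -> TrialRecording:
    """Simulate one trial: static rest, minimum-jerk reach, hold at target.

    Returns a :class:`TrialRecording` whose first ``true_onset_sample``
    samples contain only the stance baseline (gravity projection, stance
    motion, sensor noise).
    """
    _validate_params(params)
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate_hz
    dt_inv = fs

    n_onset = int(round(params.static_delay_s * fs))
    n_move = int(np.ceil(params.movement_duration_s * fs))
    n_hold = int(round(params.hold_s * fs))
    n_total = max(n_onset + n_move + n_hold, 1)
    t = np.arange(n_total) / dt_inv
    t_onset = n_onset / dt_inv
    duration = params.movement_duration_s

    # The twist jitter is drawn before pose resolution so that explicitly
    # posed and default-posed trials consume rng draws in a fixed order.
    twist_jitter = rng.normal(size=3)

    if params.start_pos is None or params.target_pos is None:
        p0, e0, p1, e1 = default_poses(params.label, params.stance, rng)
        if params.start_pos is not None:
            p0 = np.asarray(params.start_pos, dtype=float)
        if params.start_euler is not None:
            e0 = np.asarray(params.start_euler, dtype=float)
        if params.target_pos is not None:
            p1 = np.asarray(params.target_pos, dtype=float)
        if params.target_euler is not None:
            e1 = np.asarray(params.target_euler, dtype=float)
    else:
        p0 = np.asarray(params.start_pos, dtype=float)
        e0 = np.asarray(params.start_euler if params.start_euler is not None else np.zeros(3), dtype=float)
        p1 = np.asarray(params.target_pos, dtype=float)
        e1 = np.asarray(params.target_euler if params.target_euler is not None else e0, dtype=float)

    dp = p1 - p0
    de = e1 - e0
    moving = (np.linalg.norm(dp) + np.linalg.norm(de)) > 1e-12

    tau = (t - t_onset) / duration
    s, ds, d2s = minimum_jerk(tau)

    # Reach kinematics.
    acc_world = np.outer(d2s / duration**2, dp)          # m/s^2
    euler = e0[None, :] + np.outer(s, de)                # deg
    euler_rate = np.outer(ds / duration, de)             # deg/s

    # Contact-release twist: small, fast rotation transient at onset,
    # oriented along the impending reach rotation (the jolt is the abrupt
    # first correction toward the target pose) with some directional jitter.
    if moving and params.onset_twist_rate_dps > 0:
        base = de / np.linalg.norm(de) if np.linalg.norm(de) > 1e-12 else twist_jitter
        twist_dir = base + 0.3 * twist_jitter / max(np.linalg.norm(twist_jitter), 1e-12)
        twist_dir /= np.linalg.norm(twist_dir)
        tm = np.maximum(t - t_onset, 0.0)
        active = t >= t_onset
        amp = params.onset_twist_rate_dps * params.onset_twist_tau_s
        decay = np.exp(-tm / params.onset_twist_tau_s)
        angle = np.where(active, amp * (1.0 - decay), 0.0)
        rate = np.where(active, params.onset_twist_rate_dps * decay, 0.0)
        euler = euler + np.outer(angle, twist_dir)
        euler_rate = euler_rate + np.outer(rate, twist_dir)

    # Stance baseline.
    if params.stance == "walking":
        cad = params.walking_cadence_hz
        freqs_pos = np.array([cad / 2.0, cad, cad])
        freqs_eul = np.array([cad / 2.0, cad, cad / 2.0])
        ph_pos = rng.uniform(0, 2 * np.pi, 3)
        ph_eul = rng.uniform(0, 2 * np.pi, 3)
        wp = 2 * np.pi * freqs_pos
        we = 2 * np.pi * freqs_eul
        arg_p = np.outer(t, wp) + ph_pos
        arg_e = np.outer(t, we) + ph_eul
        acc_world = acc_world - _WALK_POS_AMP_M * wp**2 * np.sin(arg_p)
        euler = euler + _WALK_EULER_AMP_DEG * np.sin(arg_e)
        euler_rate = euler_rate + _WALK_EULER_AMP_DEG * we * np.cos(arg_e)

    gyro = _euler_to_body_rates(euler, euler_rate)

    # Specific force in the sensor frame, in g units.
    rot = Rotation.from_euler(
        "ZYX", np.column_stack([euler[:, 2], euler[:, 1], euler[:, 0]]), degrees=True
    )
    accel = rot.apply(acc_world + np.array([0.0, 0.0, G0]), inverse=True) / G0

    if params.noise_sd_accel > 0:
        accel = accel + rng.normal(0.0, params.noise_sd_accel, accel.shape)
    if params.noise_sd_gyro > 0:
        gyro = gyro + rng.normal(0.0, params.noise_sd_gyro, gyro.shape)
    if params.noise_sd_euler > 0:
        euler = euler + rng.normal(0.0, params.noise_sd_euler, euler.shape)

    channels = np.column_stack(
        [accel, gyro, euler[:, 1], euler[:, 0], euler[:, 2]]
    )
    return TrialRecording(
        participant_id="P000",
        run=1,
        stance=params.stance,
        label=params.label,
        sample_rate_hz=fs,
        channels=channels,
        true_onset_sample=n_onset,
    )


def draw_movement_duration(
    rng: np.random.Generator, mean: float = 1.2, sd: float = 0.15, floor: float = 0.6
) -> float:
    """Draw a movement duration (s): normal(mean, sd) floored at ``floor``."""
    return float(max(floor, rng.normal(mean, sd)))


def simulate_dataset(
    n_participants: int,
    trials_per_condition: int = 10,
    runs: Sequence[int] = (1, 2),
    stances: Sequence[str] = STANCES,
    seed: int = 0,
    static_delay_range_s: tuple[float, float] = (0.2, 1.0),
    duration_mean_s: float = 1.2,
    duration_sd_s: float = 0.15,
    **gesture_overrides,
):
    """Simulate a full collection: per participant, runs x stances x (touch
    + non-touch) x ``trials_per_condition`` trials (default 2 x 3 x 2 x 10 =
    120, matching the collection protocol).

    Per-participant kinematic idiosyncrasies (movement-speed scale, target
    offsets) are drawn once per participant so that participant-wise dataset
    splitting is meaningful.  Returns ``(trials, manifest)`` where manifest is
    a :class:`pandas.DataFrame`; see :mod:`facetouch.dataset_io`.
    """
    import pandas as pd

    if n_participants < 0:
        raise ValueError("n_participants must be >= 0")

    trials: list[TrialRecording] = []
    rows = []
    children = np.random.SeedSequence(seed).spawn(max(n_participants, 1))
    for p in range(n_participants):
        pid = f"P{p + 1:03d}"
        prng = np.random.default_rng(children[p])
        dur_scale = float(np.clip(prng.normal(1.0, 0.08), 0.8, 1.2))
        pos_off = prng.normal(0.0, 0.02, 3)
        eul_off = prng.normal(0.0, 3.0, 3)
        for run in runs:
            for stance in stances:
                for label in ("face_touch", "no_touch"):
                    for k in range(trials_per_condition):
                        trial_seed = int(prng.integers(0, 2**31))
                        trng = np.random.default_rng(trial_seed)
                        p0, e0, p1, e1 = default_poses(label, stance, trng)
                        params = GestureParams(
                            label=label,
                            stance=stance,
                            static_delay_s=float(trng.uniform(*static_delay_range_s)),
                            movement_duration_s=dur_scale
                            * draw_movement_duration(trng, duration_mean_s, duration_sd_s),
                            start_pos=p0,
                            start_euler=e0,
                            target_pos=p1 + pos_off,
                            target_euler=e1 + eul_off,
                            seed=int(trng.integers(0, 2**31)),
                            **gesture_overrides,
                        )
                        rec = simulate_trial(params)
                        rec.participant_id = pid
                        rec.run = run
                        rec.trial_id = f"{pid}_r{run}_{stance}_{label}_{k:02d}"
                        trials.append(rec)
                        rows.append(
                            {
                                "trial_id": rec.trial_id,
                                "participant_id": pid,
                                "run": run,
                                "stance": stance,
                                "label": label,
                                "n_samples": rec.n_samples,
                                "true_onset_sample": rec.true_onset_sample,
                                "file": "",
                            }
                        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "participant_id",
            "run",
            "stance",
            "label",
            "n_samples",
            "true_onset_sample",
            "file",
        ],
    )
    return trials, manifest


# ---------------------------------------------------------------------------
# Psychophysics sessions
# ---------------------------------------------------------------------------

MODALITIES = ("vibrotactile", "auditory", "visual")

#: Published per-modality response-time distributions (ms).
DEFAULT_RT_MEAN_MS = {"vibrotactile": 427.3, "auditory": 520.97, "visual": 561.70}
DEFAULT_RT_SD_MS = {"vibrotactile": 110.88, "auditory": 182.67, "visual": 173.15}


@dataclass
class PsychSessionParams:
    """One participant's feedback session: 100 trials, 30% with a sensory
    stimulus split evenly across visual / auditory / vibrotactile."""

    n_trials: int = 100
    feedback_fraction: float = 0.30
    rt_mean_ms: dict = field(default_factory=lambda: dict(DEFAULT_RT_MEAN_MS))
    rt_sd_ms: dict = field(default_factory=lambda: dict(DEFAULT_RT_SD_MS))
    rt_shift_ms: float = 0.0           # participant-level offset (all modalities)
    rt_floor_ms: float = 50.0
    movement_duration_mean_s: float = 1.2
    movement_duration_sd_s: float = 0.15
    reach_distance_m: float = 0.45
    contact_frac: float = 0.95         # face intercepts the reach at this tau
    stimulus_onset_range_s: tuple[float, float] = (0.08, 0.25)
    stop_ramp_s: float = 0.05          # braking ramp ahead of the full stop
    sample_rate_hz: float = SAMPLE_RATE_HZ
    participant_id: str = "S00"
    seed: int = 0


@dataclass
class PsychTrial:
    """A feedback trial's kinematic trace and ground truth.

    ``speed`` is the signed velocity along the approach axis (m/s); positive
    toward the face.  ``stimulus_onset_ms`` is ``None`` for no-feedback
    trials.  ``rt_true_ms`` is the generator's drawn response time and
    ``success_true`` whether the stop beat face contact (always ``False`` for
    no-feedback trials, which end in a face touch by design).
    """

    participant_id: str
    trial_index: int
    modality: str
    stimulus_onset_ms: float | None
    t_ms: np.ndarray
    speed: np.ndarray
    movement_end_ms: float
    rt_true_ms: float | None = None
    success_true: bool = False


def feedback_counts(n_trials: int, feedback_fraction: float) -> dict[str, int]:
    """Per-modality feedback-trial counts by largest remainder."""
    if not 0.0 <= feedback_fraction <= 1.0:
        raise ValueError("feedback_fraction must be in [0, 1]")
    n_fb = int(round(n_trials * feedback_fraction))
    base, rem = divmod(n_fb, 3)
    counts = {m: base for m in MODALITIES}
    if rem:
        warnings.warn(
            f"{n_fb} feedback trials not divisible by 3; "
            "assigning remainder by modality order",
            stacklevel=2,
        )
        for m in MODALITIES[:rem]:
            counts[m] += 1
    return counts


def simulate_psych_session(params: PsychSessionParams) -> list[PsychTrial]:
    """Simulate one session of face-touch trials with occasional stimuli.

    Feedback trials carry a kinematic trace in which the hand brakes to a
    complete stop at ``stimulus_onset + drawn response time`` when that beats
    face contact; otherwise (and on every no-feedback trial) the trace runs
    into the face at ``movement_end_ms``.
    """
    rng = np.random.default_rng(params.seed)
    counts = feedback_counts(params.n_trials, params.feedback_fraction)
    n_none = params.n_trials - sum(counts.values())
    order = [m for m in MODALITIES for _ in range(counts[m])] + ["none"] * n_none
    order = [order[i] for i in rng.permutation(len(order))]

    fs = params.sample_rate_hz
    trials: list[PsychTrial] = []
    for idx, modality in enumerate(order):
        d = max(0.6, rng.normal(params.movement_duration_mean_s, params.movement_duration_sd_s))
        t_contact = params.contact_frac * d
        vmax_coef = params.reach_distance_m / d

        if modality == "none":
            onset_s, rt_ms, t_stop, success = None, None, None, False
        else:
            onset_s = rng.uniform(*params.stimulus_onset_range_s)
            rt_ms = max(
                params.rt_floor_ms,
                rng.normal(params.rt_mean_ms[modality] + params.rt_shift_ms,
                           params.rt_sd_ms[modality]),
            )
            t_stop = onset_s + rt_ms / 1000.0
            success = t_stop < t_contact

        t_end = (t_stop if success else t_contact) + 0.3
        n = int(np.ceil(t_end * fs)) + 1
        t = np.arange(n) / fs
        tau = np.clip(t / d, 0.0, 1.0)
        v = vmax_coef * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)

        if success:
            ramp0 = t_stop - params.stop_ramp_s
            v_ramp0 = vmax_coef * (
                30 * (ramp0 / d) ** 2 - 60 * (ramp0 / d) ** 3 + 30 * (ramp0 / d) ** 4
            )
            in_ramp = (t >= ramp0) & (t < t_stop)
            v = np.where(in_ramp, v_ramp0 * (t_stop - t) / params.stop_ramp_s, v)
            v = np.where(t >= t_stop, 0.0, v)
        else:
            v = np.where(t >= t_contact, 0.0, v)

        trials.append(
            PsychTrial(
                participant_id=params.participant_id,
                trial_index=idx,
                modality=modality,
                stimulus_onset_ms=None if onset_s is None else onset_s * 1000.0,
                t_ms=t * 1000.0,
                speed=v,
                movement_end_ms=t_contact * 1000.0,
                rt_true_ms=rt_ms,
                success_true=success,
            )
        )
    return trials


def simulate_psych_study(
    n_participants: int = 30,
    base_params: PsychSessionParams | None = None,
    rt_between_sd_ms: float = 30.0,
    seed: int = 0,
) -> list[list[PsychTrial]]:
    """Simulate a multi-participant study; each participant gets a stable
    response-time offset (between-subject variability) applied to all
    modalities, preserving the within-subject modality effects."""
    base = base_params if base_params is not None else PsychSessionParams()
    children = np.random.SeedSequence(seed).spawn(max(n_participants, 1))
    sessions = []
    for p in range(n_participants):
        prng = np.random.default_rng(children[p])
        params = replace(
            base,
            participant_id=f"S{p + 1:02d}",
            rt_shift_ms=float(prng.normal(0.0, rt_between_sd_ms)),
            seed=int(prng.integers(0, 2**31)),
        )
        sessions.append(simulate_psych_session(params))
    return sessions
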