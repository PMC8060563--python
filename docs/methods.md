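# Methods

## The task

A wrist-worn IMU samples nine channels at 90.9 Hz (one sample every 11 ms):
3-axis specific force in g, 3-axis angular rate in deg/s, and the
device-computed Euler angles pitch/roll/yaw in degrees. A *trial* is one
hand gesture: a variable static rest segment, then a reach that either ends
on the face (positive class) or somewhere else (negative class), performed
while sitting, standing, or walking. The system's question is predictive:
given only the first `window_ms` of movement, will this reach touch the
face? The window size is the central trade-off — a longer window is more
accurate but leaves the wearer less time to react, against a mean
movement duration of about 1,200 ms and human response times of roughly
430–560 ms depending on feedback modality.

## Gesture simulator

The generator produces recordings with the statistical structure the
pipeline assumes, so every stage is testable without access to human
recordings.

**Reach kinematics.** Point-to-point reaches follow the minimum-jerk model,
the standard description of unconstrained human reaching: position moves
from start to target along `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵` with τ = t/D, and the
sensor-frame orientation interpolates its Euler angles along the same
profile. Movement durations are drawn per trial from N(1.2 s, 0.15 s),
floored at 0.6 s; static delays are uniform on 0.2–1.0 s. The ground-truth
onset sample is always `round(static_delay × 90.9)`.

**Sensor model.** All channels are mutually consistent with one analytic
trajectory: the accelerometer reads `Rᵀ(a_world − g)/g₀` (so a resting flat
sensor reads +1 g on z), the gyroscope reads the exact body rates derived
from the Euler-angle rates, and the angle channels are the ground-truth
Euler angles. Additive Gaussian noise defaults: accel 0.02 g, gyro
1.5 deg/s, angles 0.1 deg — typical consumer-IMU figures. With noise
disabled, rotating the accelerometer back to the world frame, removing
gravity, and double-integrating reproduces the analytic displacement; the
test suite verifies this to 1e-6 relative error using piecewise spline
integration split at the movement's known onset/offset kinks (a single
global quadrature cannot pass through the acceleration kink at better than
O(h²)).

**Onset transient.** Trials start with the hand resting on a surface, and
breaking that contact produces a brief rotation jolt in real IMU data; an
ideal minimum-jerk profile instead starts with mathematically zero velocity
and acceleration, which no threshold detector could localize to a few
samples. The simulator therefore adds a small exponentially decaying
rotation transient at onset (initial rate 20 deg/s, time constant 120 ms,
total angle ≈ 2.4°), oriented along the impending reach rotation with
directional jitter. It is part of the orientation profile, so accelerometer,
gyro, and angle channels stay mutually consistent and the physics oracle is
unaffected.

**Stances.** Sitting and standing differ in start pose; walking adds a
periodic baseline at the default 1.8 Hz cadence — vertical bounce
(≈ 0.026 g), lateral sway, and a wrist wobble of ±0.3° (≈ 3 deg/s rate).
The amplitudes model the protocol's tethered, indoor walking with the
instrumented hand held ready, not free arm swing.

**Targets.** Face reaches end at a stance-specific face pose (~75° pitch
rotation). Non-touch reaches mix three target families: a table/object
reach (40%), a sideways reach (35%), and a head-adjacent gesture such as an
ear scratch (25%) whose path diverges from a face touch only late — the
realistic hard negatives that make short windows genuinely harder than long
ones. Per-participant idiosyncrasies (speed scale SD 8%, target offsets
SD 2 cm / 3°) are drawn once per participant, which is what makes
participant-wise splitting meaningful.

## Preprocessing

1. **Onset detection** automates what was originally done by inspecting
   averaged plots: the first index where the gyro magnitude exceeds
   `baseline mean + 4 × baseline SD` for 5 consecutive samples, with the
   baseline taken from the first 200 ms. Returns 0 with a warning when
   nothing sustained is found. On default-noise synthetic trials the
   detector lands within ±3 samples (33 ms) of ground truth in ≥ 95% of
   trials across all stances.
2. **Feature selection** keeps accel x/y/z, gyro x/y/z, and pitch; roll and
   yaw carry no discriminative pattern for face touching and are dropped
   (depth 9 → 7).
3. **Windowing** anchors a fixed window of `W = round(window_ms × 90.9/1000)`
   samples at the detected onset — the *first* `window_ms` of movement, as
   prediction-before-touch semantics require. Gestures with fewer than W
   post-onset samples are dropped and counted.
4. **Augmentation** (training partition only, enforced) emits up to N extra
   windows per gesture shifted forward by `i × shift_step` samples
   (defaults N = 10, step = 1), each only when enough samples remain; the
   window count obeys `Σ (1 + feasible shifts)` exactly.
5. **FFT stacking** appends the magnitude of the length-W DFT of each raw
   channel (bin order 0..W−1), giving n × W × 14 tensors; verified against
   a brute-force O(W²) DFT to 1e-9.
6. **Standardization** is per channel, pooled over windows and time steps,
   computed on the training set only; the same statistics transform the
   test set and are retained for deployment. Zero-variance channels are
   floored at SD 1e-12 with a warning.

## Classifier

The 1D-CNN is `conv(64, k8) → ReLU → BN → maxpool(2) → dropout(0.8) →
conv(128, k8) → ReLU → BN → dropout(0.9) → flatten → dense(256) →
dropout(0.8) → dense(2)`, valid padding (minimum window 23 samples; flatten
width `128 × ((W−7)//2 − 7)`), trained with Adam (lr 0.001, batch 512) on
categorical cross-entropy. Batch normalization follows the activation, in
the order the architecture lists the layers. Dropout rates are the fractions
dropped. Two activation layouts are first-class:

- `conventional` (default): ReLU on the hidden dense layer, softmax on the
  2-unit output — the standard pairing with a cross-entropy loss.
- `softmax_hidden`: softmax on the hidden 256-unit layer and ReLU on the
  output; the non-negative output scores are
  L1-normalized into probabilities for the loss. This layout trains, but
  the hidden softmax throttles gradient flow and it converges visibly
  worse — which is exactly why the conventional layout is the default.

The layers live in `facetouch._nn`, a small NumPy core (im2col convolution,
batch-norm with running statistics, inverted dropout, Adam with bias
correction) whose backward passes are verified against central differences
to ~1e-9. Everything is float32 and driven by one `numpy.random.Generator`,
so fixed seeds give bit-identical training runs. A 3/4/5-convolution-layer
variant is available through `extra_conv_layers`.

The default epoch count is 60 — a desk-scale setting chosen so a full
train/evaluate cycle completes in minutes on one CPU core; the full recipe
of 300 epochs is available via `epochs=300`. Early stopping is deliberately
not used (the training recipe is a fixed epoch budget).

**Evaluation** reports counts, the row-normalized confusion matrix (rows
sum to 1 within 1e-12), accuracy, sensitivity `TP/(TP+FN)` and specificity
`TN/(TN+FP)` with face touch as the positive class, and median single-window
inference latency. `evaluate` refuses any test tensor whose participants
intersect the training participants. Note that a normalized matrix
of [[0.97, 0.03], [0.11, 0.89]] implies sensitivity 0.89 and specificity
0.97 under these definitions; the report exposes the arithmetic so either
convention can be read off.

**Window sweep.** `sweep_window` re-runs prep → train → evaluate per window
size and seed over the canonical 440–990 ms grid (51 sizes, 11 ms steps),
skipping infeasible sizes with a log entry. Both the participant split and
the weight initialization vary with the seed.

## Psychophysics analysis

Feedback sessions have 100 trials per participant: 70 without a stimulus
(these end in a face touch by design) and 10 per modality (visual,
auditory, vibrotactile), in seeded shuffled order. The simulator draws
response times from per-modality normal distributions — defaults
vibrotactile 427.3 ± 110.88 ms, auditory 520.97 ± 182.67 ms, visual
561.70 ± 173.15 ms, floored at 50 ms — plus a per-participant offset
(SD 30 ms) that models between-subject variability while preserving the
within-subject effects. The stimulus arrives uniformly 80–250 ms into the
movement (early in the reach, as a deployed predictor would deliver it;
this also keeps censoring of slow responses negligible, < 3%, so recovered
means are essentially unbiased). A trial succeeds when
`stimulus onset + response time` beats face contact, modeled at 95% of the
nominal movement span — the face intercepts the reach while the hand still
moves at ≈ 3.6% of peak speed, so failed trials never dip below the stop
threshold before contact.

**Extraction** operationalizes "complete stop or direction reversal" as the
earlier of (a) speed below 2% of the post-stimulus peak sustained for 3
samples, and (b) a sign change of the approach-axis velocity; only events
before face contact count, otherwise the trial is a failure. The result is
translation-invariant and floored at 0 ms.

**Statistics** use participant-mean response times (the standard unit for a
repeated-measures design; trial-level modeling is a deliberate non-choice
recorded here): D'Agostino–Pearson normality per modality, one-way
repeated-measures ANOVA with modality as the within-subject factor
(Greenhouse–Geisser-corrected p when Mauchly's test gives p < 0.05), and
Holm-corrected pairwise paired t-tests. The library-backed ANOVA is checked
in the tests against a first-principles sum-of-squares implementation
(`rm_anova_F`), which also powers the permutation-null uniformity check.
Incomplete within-participant designs raise with an instruction to exclude
listwise.

## Problem sizes in the test suite

The checks run at sizes chosen to finish in minutes on one core while still
being informative: protocol arithmetic at the full 40 participants
(simulation only), learning checks on 12 participants (≈ 13,000 augmented
training windows at 550 ms, 60 epochs, held-out accuracy floor 0.90), the
window-size trend on 8 participants × 2 window endpoints × 3 seeds × 20
epochs, onset recovery on 100 trials, and psychophysics power over 100
replicate 30-participant studies (feedback-only sessions in the replicate
loop, since no-feedback trials carry no response-time information).

## What passing tests do and do not show

The simulator produces cleaner, lower-dimensional structure than human
recordings: noise is stationary and Gaussian, reaches are exactly minimum
jerk, and class overlap comes only from the designed target families and
sensor noise. Consequently the classifier saturates near accuracy 1.0 at
550 ms windows on synthetic data, where the real-data figure at that window
is around 0.92 — passing the ≥ 0.90 floor shows the pipeline learns and
generalizes across held-out participants, not that it would reach any
particular accuracy on real recordings. The same caveat applies in reverse
to the window-size trend: on synthetic data the rise from 440 ms to 990 ms
is present but compressed. Real-data properties that the simulator does not
attempt: sensor drift and bias walk, magnetometer-free yaw drift,
non-stationary tremor, heterogeneous per-user gesture vocabularies, and
mislabeled trials.

## Numerical choices

- ms→samples conversion is `round(ms × 90.9/1000)`, 0-based, half-open
  windows `[start, start + W)`.
- Confusion rows are normalized by true-class counts; evaluation raises if
  a class is absent from the test set.
- Dropout masks, shuffling, and initialization all derive from one
  generator seeded by `random_state`; BLAS reductions are order-stable, so
  identical seeds reproduce losses bit-for-bit.
- Training aborts with diagnostics on a non-finite loss rather than
  continuing silently; inputs that do not look standardized trigger a
  warning, not an error.
- The duration distribution is floored (truncated) at 0.6 s; at 4 SD below
  the mean the clip is a measure-zero correction in practice.
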