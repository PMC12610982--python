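# Methods

This note documents the models, conventions and design choices behind
`fmaue`, in the spirit of a package methods appendix: what each stage
assumes, which knobs matter, and what the synthetic experiments do and do not
demonstrate.

## Problem setting

The target is the clinician-rated FMA-UE, split into Part A shoulder/elbow
(0–36), Part B wrist (0–10), Part C hand (0–14) and Part D coordination/speed
(0–6). Inputs are seven specialized motion trials per subject (RU, RKE, HTS,
EPS, WC, HMFE, RKN), each recorded by four IMUs (hand, forearm, upper arm,
trunk) delivering 3-axis acceleration (±8 g), angular rate (±2000 °/s) and
orientation angles at a nominal 100 Hz. Orientation angles are treated as
given (the sensors fuse them on-board); the package performs no sensor
fusion. All orientation math uses one fixed convention: angles `(ox, oy, oz)`
map to the rotation `R = Rz(oz)·Ry(oy)·Rx(ox)` (intrinsic Z-Y-X), and
relative joint rotations are decomposed by the same sequence. The
decomposition order is a declared convention — the anatomical axis names do
not pin one down.

## Synthetic cohort generator

Because no public recording of this protocol exists, the generator is a
first-class, tested component that emulates the *statistical structure* the
pipeline assumes, not limb biomechanics:

* A latent severity vector `s = (s_A, s_B, s_C, s_D) ∈ [0,1]^4` grades each
  subject; sub-scores are the deterministic map
  `score_k = round((1 − s_k)·range_k)`. The default cohort sampler draws each
  component from Beta(2, 2) and makes a subject entirely unimpaired with
  probability 0.2, mirroring a 15-subject cohort containing 4 healthy
  controls.
* Each motion has a kinematic template: a minimum-jerk out-and-back
  orientation oscillation (5 repetitions) distributed over segment axes by a
  per-motion gain table, with base amplitudes of 45–100° and base repetition
  periods of 1.6–2.2 s chosen so unimpaired trials last roughly 8–11 s.
* Impairment acts through a per-motion coupling vector `w` (dominant part
  weight 0.7, remainder on the other parts the motion touches; 1.0 for
  single-part motions): effective amplitude `= base·(1 − 0.8·w·s)`,
  repetition period `= base·(1 + w·s)` (slowing), and additive band-limited
  3–8 Hz tremor on the involved orientation axes with standard deviation
  `2° · (w·s)` scaled by segment involvement. Tremor in the 3–8 Hz band is
  the classic postural/kinetic tremor range.
* Gyro is the exact time-derivative of orientation plus white noise
  (0.5 °/s); acceleration is the gravity direction rotated into the sensor
  frame plus a 0.25 m lever-arm angular-acceleration term and white noise
  (0.01 g) — plausible consumer-IMU noise floors, both configurable.

What the generator does **not** emulate: compensatory trunk strategies beyond
a small amplitude leak, inter-session sensor placement variability, soft
tissue artifacts, fatigue, or the discrete item-by-item structure of the real
scale. Passing the recovery experiments therefore shows that the pipeline can
extract a planted impairment gradient from realistic signal families
(amplitude loss, slowing, tremor) — it is not evidence about clinical
accuracy.

## Conditioning

* **Outliers**: Hampel rule per channel — samples with
  `|x − median| > z·1.4826·MAD` (default z = 3) are replaced by the mean of
  the inliers. If every sample is flagged the series is returned unchanged
  with a warning.
* **Filtering**: zero-phase (forward–backward) Butterworth, order 4. Two
  presets ship. `PAPER_FAITHFUL` realizes a literal 10–50 Hz band-pass at
  100 Hz sampling (high-pass 10 Hz + low-pass 49.9 Hz); note this removes the
  sub-10 Hz band where voluntary movement lives, so it is kept only for
  protocol fidelity. `FUNCTIONAL` (0.25–10 Hz) retains voluntary motion and
  the tremor band and is the default in synthetic experiments; reports name
  the preset used. The configured band applies to acceleration and gyro;
  orientation receives only the low-pass corner because its DC component
  (posture) is required by joint angles and gravity reasoning.
* **Resampling**: linear interpolation onto a uniform 100 Hz grid.
* **Joint angles**: for hand–forearm, forearm–upper-arm and upper-arm–trunk
  pairs, `R_rel(t) = R_prox(t)^{-1}·R_dist(t)`, left-re-referenced by the
  neutral sample so angles start at zero; a neutral pose whose middle
  decomposition angle is within 0.5° of ±90° raises a gimbal-lock error
  naming the pair.
* **Augmentation** (training data; a held-out subject's copies serve only as
  extra test samples for mean aggregation): per copy, Gaussian noise
  (σ = 0.02 × channel std), one global time-warp factor from [0.9, 1.1]
  (cubic re-interpolation onto the grid), one amplitude factor from
  [0.8, 1.2]. A single warp/amplitude pair per copy keeps the four segments
  kinematically consistent. Default 3 copies per trial.
* **Windows**: 2 s, 50 % overlap, trailing partial window dropped.

## Feature registry: 1530 = 153 × 10

The registry is a declared, versioned convention (`fmaue-153x10-v1`): per IMU
18 base channels — acc x/y/z, gyro x/y/z, orientation x/y/z, orientation
acceleration (second difference × rate²), angular difference (first
difference × rate), inclination ratio (orientation minus trunk orientation;
for the trunk, minus its neutral orientation) — each paired with its first
difference (36 per segment), plus 9 joint-angle channels: 4·36 + 9 = 153.
Ten statistics per channel: mean, population std, rms, amplitude
((max−min)/2), max, min, range (max−min), approximate entropy, median, IQR.
Feature order is channel-major/statistic-minor and the index ↔
(channel, statistic) map is bijective; alternative decompositions totaling
1530 can be dropped in by replacing the registry.

Approximate entropy uses the classical definition
`ApEn = Φ_m(r) − Φ_{m+1}(r)` with Chebyshev distance, self-matches included,
m = 2 and r = 0.2·σ per window per channel; σ = 0 returns 0 by convention.
The implementation counts matches on exact float64 boolean match matrices and
is tested to 1e-10 against an O(N²m) brute-force oracle.

Per-motion window counts vary with trial length; tensors are fixed at
WL = 9 windows (a 10 s trial at 100 Hz) by central cropping or by repeating
the last window, with padding recorded in a mask that excludes padded slots
from encoder pooling and normalization fitting.

## Estimator

Encoder: one LSTM (1530 → 256) shared across the seven motions — the
parameter-efficient reading of a single recurrent layer — followed by a
masked temporal mean over WL steps and a linear 256 → 128 map, giving the
latent `[7, 128]`. Predictor: one LSTM over the 7-step latent sequence
(hidden kept at 128); the final hidden state passes through dropout 0.3 and a
linear 128 → 4 layer. Motion order is part of the model contract.

Scores are normalized to [0, 1] by the part ranges for the loss (keeping MSE
scale-balanced across parts) and de-normalized and clipped to [0, range] only
at reporting time. Features are z-scored with statistics fitted on the
training fold only.

Mixup pairs are formed by a random within-batch permutation and applied with
probability `apply_prob` per batch (default 1.0; 0 recovers plain MSE
regression exactly, the no-mixup ablation arm). λ ~ Beta(α, α) with α = 1.

Default hyperparameters mirror the reference protocol (epochs 100,
lr 5e-5, batch 8, Adam defaults, no weight decay or schedule, uniform fan-in
initialization, seed-controlled). For the *synthetic recovery preset* the
package uses lr 3e-3, batch 4 and 30 epochs: at cohort scale a fold sees only
~10² gradient steps, and Adam's per-step displacement is bounded by the
learning rate, so 5e-5 cannot move the parameters appreciably within that
budget; the larger rate is a trainability choice made from training-loss
behaviour. Training computes in float32; gradient checks run in float64.

## Evaluation protocol and metric conventions

LOSOCV trains one freshly initialized model per subject on all others
(augmented) and predicts the held-out subject as the mean over that subject's
test samples. Fold seeds derive deterministically from the master seed plus
the subject id, so ablation arms share fold randomness. A failed fold is
recorded and the remaining results returned.

NMAE and NRMSE divide by the part's full range (36, 10, 14, 6; 66 for the
total) — uniformly, for every metric. "Overall" metrics pool the normalized
(score/range) pairs of all parts. Pearson significance is two-sided at
α = 0.05. Constant-truth parts report correlation and R² as not applicable
rather than NaN.

The motion-contribution map is permutation importance: for each motion the
corresponding tensor rows are permuted across subjects and the mean increase
in per-part absolute error (floored at 0, averaged over repeats) is
normalized per part to sum 1. This is a declared stand-in for an unspecified
attribution procedure and is labelled as such in outputs. Note that it is
informative only when subjects genuinely differ in the permuted motion; with
i.i.d.-noise inputs the final-step readout makes the model most sensitive to
the last motion in the sequence regardless of signal.

## Problem sizes of the shipped experiments

The default test-suite and acceptance-script experiments use: recovery —
15 subjects, 1 augmented copy per trial, 30 epochs per fold, functional
filter preset; ablation direction — 10 subjects with only Part-A severity
varying (a planted gradient), no augmentation, 30 epochs, full set vs.
`__B*C*D*`. These sizes are the package's chosen desk-scale defaults; an
extended run (30 subjects, full 100 epochs, 3 copies) is provided as
`examples/extended_recovery.py` and takes several hours.

## Known limitations

* The 153 × 10 decomposition is one consistent realization of a 1530-feature
  registry, not a canonical fact about any external dataset.
* The NRMSE range-divisor convention is applied uniformly; other
  normalizations (e.g. by observed score spread) would change NRMSE but not
  MAE/RMSE/R²/r.
* Synthetic recovery quality depends on the planted coupling between
  severities and motions; parts expressed through a single short motion
  (B, C) generalize across subjects less reliably at n = 15 than Part A,
  which four motions carry.
* The numpy training loop is single-threaded and CPU-bound; it is sized for
  desk-scale cohorts, not large-scale training.
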