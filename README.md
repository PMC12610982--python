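# fmaue — FMA-UE sub-score estimation from wearable IMU data

`fmaue` estimates the four sub-scores of the Fugl–Meyer Assessment for the
Upper Extremity (FMA-UE) — Part A shoulder/elbow (0–36), Part B wrist (0–10),
Part C hand (0–14), Part D coordination/speed (0–6), total 0–66 — from
wearable-sensor recordings of seven specialized upper-limb motions:

| Motion | Name | Chiefly probes |
|---|---|---|
| RU | reaching upward | A |
| RKE | reaching knee to ear | A |
| HTS | hand to lumbar spine | A |
| EPS | elbow pronation–supination | A |
| WC | wrist circumduction | B |
| HMFE | hand mass flexion/extension | C |
| RKN | reaching knee to nose | D |

Each motion trial is recorded by four IMUs (hand, forearm, upper arm, trunk;
3-axis acceleration ±8 g, gyro ±2000 °/s, orientation angles) at 100 Hz.
The package is aimed at researchers in sensor-based rehabilitation assessment
who want a fully testable, self-contained reimplementation of this style of
pipeline — including a synthetic impairment-graded cohort simulator, so no
clinical data are required to run, test, or extend any stage.

## Method

1. **Conditioning** — Hampel outlier replacement, zero-phase Butterworth
   filtering (configurable presets), resampling to 100 Hz, wrist/elbow/
   shoulder joint angles from relative segment rotations referenced to a
   neutral pose, signal-level augmentation (Gaussian noise, time-warp,
   amplitude scaling 0.8–1.2), and 2 s / 50 %-overlap sliding windows.
2. **Features** — a fixed registry of 153 channels (per IMU: acc, gyro,
   orientation, orientation acceleration, angular difference, trunk-referenced
   inclination, each with its first difference; plus 9 joint-angle channels)
   × 10 statistics (mean, std, rms, amplitude, max, min, range, approximate
   entropy, median, IQR) = **1530 features per window**, assembled into a
   per-subject tensor `x ∈ R^{7 × WL × 1530}`.
3. **Estimator** — mixup augmentation
   `x̂ = λ x_i + (1−λ) x_j`, `ŷ = λ y_i + (1−λ) y_j`, `λ ~ Beta(α, α)`, α = 1,
   feeding an LSTM autoencoder (1530 → 256 hidden per window step, masked mean
   pool over WL, linear 256 → 128 ⇒ latent `[7, 128]`) and an LSTM predictor
   over the 7 motion latents whose final state maps through dropout (0.3) and
   a linear layer to the 4 normalized sub-scores; MSE loss, Adam.
4. **Evaluation** — leave-one-subject-out cross-validation (LOSOCV) with
   per-fold re-initialization and train-only normalization; R², Pearson r,
   MAE, NMAE = MAE/range, RMSE, NRMSE = RMSE/range per part, plus pooled and
   total-score (sum, /66) metrics; reduced-motion-set ablations and a
   permutation-importance motion-contribution map.

The sequence model is implemented in numpy with hand-written reverse-mode
gradients (`fmaue.nn`), gradient-checked against numerical differentiation.

## Worked example

```python
import numpy as np
from fmaue import (simulate_cohort, losocv, compute_metrics,
                   PipelineConfig, ModelConfig, MixupConfig,
                   AugmentConfig, PreprocessConfig, FUNCTIONAL)

cohort = simulate_cohort(15, seed=1)          # 15 synthetic subjects
pipe = PipelineConfig(preprocess=PreprocessConfig(filter=FUNCTIONAL),
                      augment=AugmentConfig(copies_per_trial=1))
mcfg = ModelConfig(epochs=30, lr=3e-3, batch_size=4)
results, failures = losocv(cohort, pipe, mcfg, MixupConfig(), seed=1)
rep = compute_metrics(results)
print(f"total: r={rep.total.r:.3f} R2={rep.total.r2:.3f} "
      f"NRMSE={rep.total.nrmse:.3f}")
```

prints (about six minutes on one CPU):

```
total: r=0.850 R2=0.606 NRMSE=0.108
```

meaning: across 15 held-out subjects the predicted total FMA-UE scores
correlate with the simulated ground truth at r = 0.85, explain 61 % of its
variance, and miss by about 11 % of the 66-point scale on average — i.e. the
pipeline recovers the impairment gradient planted by the simulator from raw
synthetic IMU streams alone. Shorter narrative scripts for every capability
live in `examples/`.

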