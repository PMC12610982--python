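"""Extended parameter-recovery run: 30 subjects, full 100-epoch training.

The long-horizon version of run_losocv.py — larger cohort, the full
3-copies-per-trial augmentation and 100 epochs per fold. Expect several
hours on one CPU; intended for workstation runs, not the test suite.
"""

from fmaue import (
    AugmentConfig,
    FUNCTIONAL,
    MixupConfig,
    ModelConfig,
    PipelineConfig,
    PreprocessConfig,
    compute_metrics,
    losocv,
    simulate_cohort,
)

cohort = simulate_cohort(30, seed=1)
pipe = PipelineConfig(preprocess=PreprocessConfig(filter=FUNCTIONAL),
                      augment=AugmentConfig(copies_per_trial=3))
mcfg = ModelConfig(epochs=100, lr=3e-3, batch_size=4)

results, failures = losocv(cohort, pipe, mcfg, MixupConfig(), seed=1)
print(f"{len(results)} folds, {len(failures)} failures")
rep = compute_metrics(results)
for p in "abcd":
    m = rep.parts[p]
    print(f"part {p.upper()}: R2={m.r2:.3f} r={m.r:.3f} NRMSE={m.nrmse:.3f}")
t = rep.total
print(f"total:  R2={t.r2:.3f} r={t.r:.3f} NRMSE={t.nrmse:.3f}")
# With 2x the cohort and full training the per-part determination
# coefficients should rise well above the desk-scale run's.
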