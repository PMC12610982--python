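"""Metric suite, LOSOCV protocol, ablation table, contribution map, reports."""

import json
import math

import numpy as np
import pytest

from fmaue.estimator import MixupConfig, ModelConfig, train
from fmaue.evaluation import (
    FoldResult,
    MetricsReport,
    compute_metrics,
    losocv,
    motion_contribution,
    motion_set_presets,
    report,
    total_score,
)
from fmaue.features import N_FEATURES, FeatureTensor, fit_norm
from fmaue.session import MOTIONS, FmaSubScores, Motion
from fmaue.synthetic import ImpairmentProfile, simulate_subject


def _fold_results(true, pred):
    return [
        FoldResult(subject_id=f"S{i}", predicted=np.asarray(p, float),
                   true=np.asarray(t, float), fold_seed=i)
        for i, (t, p) in enumerate(zip(true, pred))
    ]


# ---------------------------------------------------------------------- totals

def test_total_score_values():
    assert total_score(FmaSubScores(36, 10, 14, 6)) == 66
    assert total_score((0, 0, 0, 0)) == 0
    assert total_score(np.array([10.5, 2.0, 3.0, 1.0])) == pytest.approx(16.5)


# ---------------------------------------------------------------------- metrics

def _manual_metrics(y, p, divisor):
    n = len(y)
    mae = sum(abs(a - b) for a, b in zip(p, y)) / n
    rmse = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, y)) / n)
    ybar = sum(y) / n
    ss_tot = sum((v - ybar) ** 2 for v in y)
    r2 = 1 - sum((a - b) ** 2 for a, b in zip(p, y)) / ss_tot
    pbar = sum(p) / n
    num = sum((a - ybar) * (b - pbar) for a, b in zip(y, p))
    den = math.sqrt(sum((a - ybar) ** 2 for a in y)
                    * sum((b - pbar) ** 2 for b in p))
    r = num / den
    return dict(mae=mae, rmse=rmse, r2=r2, r=r, nmae=mae / divisor,
                nrmse=rmse / divisor)


def test_metrics_match_independent_recomputation():
    rng = np.random.default_rng(0)
    true = rng.uniform(0, [36, 10, 14, 6], size=(6, 4))
    pred = true + rng.normal(0, [3, 1, 1.5, 0.5], size=(6, 4))
    rep = compute_metrics(_fold_results(true, pred))
    for i, part in enumerate("abcd"):
        want = _manual_metrics(list(true[:, i]), list(pred[:, i]),
                               [36, 10, 14, 6][i])
        got = rep.parts[part]
        for k in want:
            assert getattr(got, k) == pytest.approx(want[k], abs=1e-10), \
                (part, k)
    want_total = _manual_metrics(list(true.sum(axis=1)),
                                 list(pred.sum(axis=1)), 66.0)
    for k in want_total:
        assert getattr(rep.total, k) == pytest.approx(want_total[k],
                                                      abs=1e-10), k
    div = np.array([36, 10, 14, 6], float)
    want_overall = _manual_metrics(list((true / div).ravel()),
                                   list((pred / div).ravel()), 1.0)
    for k in want_overall:
        assert getattr(rep.overall, k) == pytest.approx(want_overall[k],
                                                        abs=1e-10), k


def test_perfect_predictions():
    rng = np.random.default_rng(1)
    true = rng.uniform(0, [36, 10, 14, 6], size=(5, 4))
    rep = compute_metrics(_fold_results(true, true.copy()))
    for part in "abcd":
        m = rep.parts[part]
        assert m.r2 == pytest.approx(1.0)
        assert m.r == pytest.approx(1.0)
        assert m.mae == m.nmae == m.rmse == m.nrmse == 0.0


def test_printed_mae_to_nmae_convention():
    """MAE / part range reproduces the published NMAE convention to 4 d.p."""
    printed = {"a": (2.7054, 0.0751, 36), "b": (1.2023, 0.1202, 10),
               "c": (1.3633, 0.0974, 14), "d": (0.4722, 0.0787, 6)}
    true = np.zeros((2, 4))
    pred = np.array([[v[0] for v in printed.values()]] * 2)
    rep = compute_metrics(_fold_results(true, pred))
    for part, (mae, nmae, div) in printed.items():
        got = rep.parts[part]
        assert got.mae == pytest.approx(mae, abs=1e-12)
        assert got.nmae == pytest.approx(nmae, abs=1e-4)


def test_constant_truth_reports_not_applicable_without_nan():
    true = np.tile([10.0, 5.0, 7.0, 3.0], (4, 1))
    pred = true + np.random.default_rng(3).normal(0, 1, true.shape)
    rep = compute_metrics(_fold_results(true, pred))
    for part in "abcd":
        m = rep.parts[part]
        assert m.r2 is None and m.r is None
        assert np.isfinite(m.mae) and np.isfinite(m.nrmse)


def test_nmae_nrmse_scale_invariance():
    rng = np.random.default_rng(4)
    true = rng.uniform(0, 10, (6, 4))
    pred = true + rng.normal(0, 1, true.shape)
    rep1 = compute_metrics(_fold_results(true, pred),
                           divisors=(36, 10, 14, 6))
    rep2 = compute_metrics(_fold_results(3 * true, 3 * pred),
                           divisors=(108, 30, 42, 18))
    for part in "abcd":
        assert rep1.parts[part].nmae == pytest.approx(
            rep2.parts[part].nmae, abs=1e-12)
        assert rep1.parts[part].nrmse == pytest.approx(
            rep2.parts[part].nrmse, abs=1e-12)


# ---------------------------------------------------------------------- losocv

def test_losocv_two_subject_cohort(fast_pipeline_cfg):
    cohort = [
        simulate_subject(ImpairmentProfile(np.array([0.1, 0.2, 0.1, 0.3])),
                         seed=1, subject_id="P01"),
        simulate_subject(ImpairmentProfile(np.array([0.7, 0.8, 0.6, 0.9])),
                         seed=2, subject_id="P02"),
    ]
    mcfg = ModelConfig(epochs=2, lr=1e-3, batch_size=2)
    results, failures = losocv(cohort, fast_pipeline_cfg, mcfg,
                               MixupConfig(apply_prob=0.0), seed=5)
    assert failures == []
    assert len(results) == 2
    assert {r.subject_id for r in results} == {"P01", "P02"}
    for r in results:
        assert np.all(r.predicted >= 0)
        assert np.all(r.predicted <= [36, 10, 14, 6])


def test_losocv_rejects_single_subject(fast_pipeline_cfg):
    s = simulate_subject(ImpairmentProfile(np.zeros(4)), seed=1)
    with pytest.raises(ValueError, match="at least 2"):
        losocv([s], fast_pipeline_cfg)


# ------------------------------------------------------------------ motion sets

def test_motion_set_presets_cover_table_rows():
    presets = motion_set_presets()
    assert set(presets) == {"A*B*C*D*", "__B*C*D*", "A*__C*D*", "A*B*__D*",
                            "A*B*C*__"}
    assert presets["A*B*C*D*"].motions == MOTIONS
    assert presets["A*B*C*__"].motions == tuple(
        m for m in MOTIONS if m is not Motion.RKN)
    assert len(presets["A*B*C*__"].motions) == 6
    assert presets["__B*C*D*"].motions == (Motion.WC, Motion.HMFE, Motion.RKN)


def test_empty_motion_set_rejected():
    from fmaue.evaluation import MotionSetSpec

    with pytest.raises(ValueError, match="at least one"):
        MotionSetSpec("none", ())


# ---------------------------------------------------------------- contribution

def _planted_training(n=12, wl=3, seed=0):
    """Subjects differ only in part-B severity, expressed in the WC row.

    The other motion rows share one template across subjects (plus sensor-like
    jitter), mirroring a cohort whose only varying impairment is the wrist.
    """
    rng = np.random.default_rng(seed)
    y = np.tile([0.5, 0.0, 0.5, 0.5], (n, 1))
    y[:, 1] = rng.random(n)
    template = 0.5 * rng.standard_normal((7, wl, N_FEATURES))
    tensors = []
    wc = MOTIONS.index(Motion.WC)
    for i in range(n):
        vals = template + 0.05 * rng.standard_normal((7, wl, N_FEATURES))
        vals[wc, :, :100] += 2.0 * y[i, 1]
        tensors.append(FeatureTensor(values=vals,
                                     mask=np.ones((7, wl), bool)))
    return tensors, y


def test_identity_permutation_gives_zero_importance():
    tensors, y = _planted_training(n=6)
    mcfg = ModelConfig(epochs=1, lr=1e-3, batch_size=3, seed=0)
    est = train(tensors, y, mcfg, MixupConfig(apply_prob=0.0))
    contrib, flags = motion_contribution(
        est, tensors, y, n_repeats=2, seed=0,
        permutations=[np.arange(6), np.arange(6)])
    np.testing.assert_array_equal(contrib, 0.0)
    assert len(flags) == 4  # every part flagged all-zero


def test_contribution_columns_normalized():
    tensors, y = _planted_training(n=8)
    mcfg = ModelConfig(epochs=5, lr=3e-3, batch_size=4, seed=1)
    est = train(tensors, y, mcfg, MixupConfig(apply_prob=0.0))
    contrib, flags = motion_contribution(est, tensors, y, n_repeats=3, seed=2)
    for k, part in enumerate("abcd"):
        if f"part_{part}" not in " ".join(flags):
            assert contrib[:, k].sum() == pytest.approx(1.0)
        assert np.all(contrib[:, k] >= 0)


def test_planted_part_b_structure_recovered_by_wc_contribution():
    tensors, y = _planted_training(n=14, seed=3)
    mcfg = ModelConfig(epochs=60, lr=3e-3, batch_size=4, seed=2, dropout=0.1)
    est = train(tensors, y, mcfg, MixupConfig(apply_prob=0.0))
    contrib, _ = motion_contribution(est, tensors, y, n_repeats=5, seed=3)
    assert np.argmax(contrib[:, 1]) == MOTIONS.index(Motion.WC)


# ---------------------------------------------------------------------- report

def test_report_files_round_trip_and_determinism(tmp_path):
    rng = np.random.default_rng(6)
    true = rng.uniform(0, [36, 10, 14, 6], size=(5, 4))
    pred = true + rng.normal(0, 1, true.shape)
    results = _fold_results(true, pred)
    metrics = compute_metrics(results)
    files = report(results, metrics, tmp_path)
    names = {f.name for f in files}
    assert {"metrics.json", "metrics.csv", "predictions.csv",
            "scatter.png"} <= names

    loaded = MetricsReport.from_dict(
        json.loads((tmp_path / "metrics.json").read_text()))
    assert loaded.to_dict() == metrics.to_dict()

    import pandas as pd
    preds = pd.read_csv(tmp_path / "predictions.csv")
    assert len(preds) == 5 * 4  # one row per (subject, part)

    before = (tmp_path / "metrics.json").read_bytes()
    report(results, metrics, tmp_path)
    assert (tmp_path / "metrics.json").read_bytes() == before
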