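"""Leave-one-subject-out evaluation, metrics, ablation and contribution maps.

LOSOCV protocol: for each subject, a fresh model is initialized, feature
normalization statistics are fitted on the remaining subjects only, the model
is trained on those subjects' (augmented) tensors, and the held-out subject's
prediction is the mean over that subject's test samples. Train and test data
are strictly disjoint by subject; augmented copies never cross the fold
boundary.

Metrics per part (A-D): R², Pearson r (two-sided p), MAE, NMAE = MAE/range,
RMSE, NRMSE = RMSE/range, with ranges (36, 10, 14, 6). Total-score metrics
use the summed parts with divisor 66; "overall" metrics pool the normalized
(score/range) pairs of all parts.

The motion-contribution map is computed by permutation importance — for each
motion, its latent input rows are permuted across subjects and the resulting
mean increase in per-part absolute error is recorded — because the importance
procedure is otherwise an open choice; outputs are labelled accordingly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .estimator import MixupConfig, ModelConfig, TrainedEstimator, train
from .features import FeatureTensor, NormStats, fit_norm, apply_norm
from .pipeline import PipelineConfig, session_variants, subject_seed
from .session import MOTIONS, PART_NAMES, PART_RANGES, FmaSubScores, Motion, SubjectSession

__all__ = [
    "FoldResult",
    "PartMetrics",
    "MetricsReport",
    "MotionSetSpec",
    "MOTION_GROUPS",
    "motion_set_presets",
    "total_score",
    "losocv",
    "compute_metrics",
    "ablate",
    "motion_contribution",
    "report",
]

_DIVISORS = np.array([PART_RANGES[p] for p in PART_NAMES], dtype=float)

#: Motion groups by the FMA-UE part they chiefly probe.
MOTION_GROUPS: dict[str, tuple[Motion, ...]] = {
    "A*": (Motion.RU, Motion.RKE, Motion.HTS, Motion.EPS),
    "B*": (Motion.WC,),
    "C*": (Motion.HMFE,),
    "D*": (Motion.RKN,),
}


@dataclasses.dataclass(frozen=True)
class MotionSetSpec:
    """A named subset of the seven motions (model input resized to match)."""

    name: str
    motions: tuple[Motion, ...]

    def __post_init__(self) -> None:
        if len(self.motions) == 0:
            raise ValueError("motion set must contain at least one motion")
        # preserve canonical order
        ordered = tuple(m for m in MOTIONS if m in self.motions)
        object.__setattr__(self, "motions", ordered)


def motion_set_presets() -> dict[str, MotionSetSpec]:
    """Named presets: full set and the four drop-one-group sets."""
    def without(group: str) -> tuple[Motion, ...]:
        excl = set(MOTION_GROUPS[group])
        return tuple(m for m in MOTIONS if m not in excl)

    return {
        "A*B*C*D*": MotionSetSpec("A*B*C*D*", MOTIONS),
        "__B*C*D*": MotionSetSpec("__B*C*D*", without("A*")),
        "A*__C*D*": MotionSetSpec("A*__C*D*", without("B*")),
        "A*B*__D*": MotionSetSpec("A*B*__D*", without("C*")),
        "A*B*C*__": MotionSetSpec("A*B*C*__", without("D*")),
    }


def total_score(scores: FmaSubScores | Sequence[float] | np.ndarray) -> float:
    """Total FMA-UE score: the sum of the four sub-scores."""
    if isinstance(scores, FmaSubScores):
        return float(scores.total)
    return float(np.sum(np.asarray(scores, dtype=float)))


@dataclasses.dataclass
class FoldResult:
    """Held-out prediction of one LOSOCV fold."""

    subject_id: str
    predicted: np.ndarray  # (4,) de-normalized sub-scores
    true: np.ndarray       # (4,)
    fold_seed: int


@dataclasses.dataclass
class FoldFailure:
    subject_id: str
    error: str


# ---------------------------------------------------------------------------
# LOSOCV
# ---------------------------------------------------------------------------

def losocv(
    cohort: list[SubjectSession],
    pipe_cfg: PipelineConfig | None = None,
    mcfg: ModelConfig | None = None,
    mixcfg: MixupConfig | None = None,
    seed: int = 0,
    motions: tuple[Motion, ...] = MOTIONS,
    precomputed: dict[str, list[FeatureTensor]] | None = None,
) -> tuple[list[FoldResult], list[FoldFailure]]:
    """Leave-one-subject-out cross-validation over a cohort.

    Returns (fold results, failures); a failed fold is recorded instead of
    aborting the whole run. ``precomputed`` may supply per-subject raw
    (unnormalized) tensor variants to reuse across ablation arms.
    """
    if len(cohort) < 2:
        raise ValueError("LOSOCV needs at least 2 subjects")
    pipe_cfg = pipe_cfg or PipelineConfig()
    mcfg = mcfg or ModelConfig()
    mixcfg = mixcfg or MixupConfig()

    if precomputed is None:
        precomputed = featurize_cohort(cohort, pipe_cfg, seed, motions)

    results: list[FoldResult] = []
    failures: list[FoldFailure] = []
    for held_out in cohort:
        fold_seed = subject_seed(seed, held_out.subject_id)
        try:
            train_tensors: list[FeatureTensor] = []
            train_scores: list[np.ndarray] = []
            for s in cohort:
                if s.subject_id == held_out.subject_id:
                    continue
                for t in precomputed[s.subject_id]:
                    train_tensors.append(t)
                    train_scores.append(s.scores.as_array())
            norm = fit_norm(train_tensors)
            xs = [apply_norm(norm, t) for t in train_tensors]
            ys = np.stack([norm.normalize_scores(v) for v in train_scores])
            fold_mcfg = dataclasses.replace(mcfg, seed=fold_seed)
            est = train(xs, ys, fold_mcfg, mixcfg, norm=norm)
            test_preds = [
                est.predict_normalized(apply_norm(norm, t))
                for t in precomputed[held_out.subject_id]
            ]
            pred_norm = np.mean(test_preds, axis=0)
            pred = np.clip(norm.denormalize_scores(pred_norm), 0.0,
                           norm.divisors)
            results.append(FoldResult(
                subject_id=held_out.subject_id,
                predicted=pred,
                true=held_out.scores.as_array(),
                fold_seed=fold_seed,
            ))
        except Exception as exc:  # noqa: BLE001 - partial results contract
            failures.append(FoldFailure(held_out.subject_id, repr(exc)))
    return results, failures


def featurize_cohort(
    cohort: list[SubjectSession],
    pipe_cfg: PipelineConfig,
    seed: int,
    motions: tuple[Motion, ...] = MOTIONS,
) -> dict[str, list[FeatureTensor]]:
    """Raw (unnormalized) tensor variants per subject, reusable across folds."""
    return {
        s.subject_id: session_variants(s, pipe_cfg, seed, motions)
        for s in cohort
    }


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PartMetrics:
    """Regression metrics of one part (or of the pooled / total scores)."""

    r2: float | None
    r: float | None
    p_value: float | None
    mae: float
    nmae: float
    rmse: float
    nrmse: float
    divisor: float
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _part_metrics(true: np.ndarray, pred: np.ndarray,
                  divisor: float) -> PartMetrics:
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    err = pred - true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
        if np.std(pred) > 0:
            r, p = sstats.pearsonr(true, pred)
            r, p = float(r), float(p)
        else:
            r, p = None, None
    else:  # constant truth: correlation and R^2 are not applicable
        r2, r, p = None, None, None
    return PartMetrics(r2=r2, r=r, p_value=p, mae=mae, nmae=mae / divisor,
                       rmse=rmse, nrmse=rmse / divisor, divisor=divisor,
                       n=len(true))


@dataclasses.dataclass
class MetricsReport:
    """Per-part, overall (pooled normalized) and total-score metrics."""

    parts: dict[str, PartMetrics]
    overall: PartMetrics
    total: PartMetrics
    divisors: tuple[float, ...] = tuple(_DIVISORS)

    def to_dict(self) -> dict:
        return {
            "parts": {k: v.to_dict() for k, v in self.parts.items()},
            "overall": self.overall.to_dict(),
            "total": self.total.to_dict(),
            "divisors": list(self.divisors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(
            parts={k: PartMetrics(**v) for k, v in d["parts"].items()},
            overall=PartMetrics(**d["overall"]),
            total=PartMetrics(**d["total"]),
            divisors=tuple(d["divisors"]),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = {k: v.to_dict() for k, v in self.parts.items()}
        rows["overall"] = self.overall.to_dict()
        rows["total"] = self.total.to_dict()
        return pd.DataFrame(rows).T


def compute_metrics(
    results: list[FoldResult],
    divisors: Sequence[float] = tuple(_DIVISORS),
) -> MetricsReport:
    """Aggregate fold results into the full metric suite."""
    if len(results) < 2:
        raise ValueError("need at least 2 fold results")
    divisors = np.asarray(divisors, dtype=float)
    true = np.stack([r.true for r in results])        # (n, 4)
    pred = np.stack([r.predicted for r in results])   # (n, 4)
    parts = {
        part: _part_metrics(true[:, i], pred[:, i], divisors[i])
        for i, part in enumerate(PART_NAMES)
    }
    pooled_true = (true / divisors).ravel()
    pooled_pred = (pred / divisors).ravel()
    overall = _part_metrics(pooled_true, pooled_pred, 1.0)
    total = _part_metrics(true.sum(axis=1), pred.sum(axis=1),
                          float(divisors.sum()))
    return MetricsReport(parts=parts, overall=overall, total=total,
                         divisors=tuple(divisors))


# ---------------------------------------------------------------------------
# Ablation over motion sets
# ---------------------------------------------------------------------------

def ablate(
    cohort: list[SubjectSession],
    set_specs: list[MotionSetSpec],
    pipe_cfg: PipelineConfig | None = None,
    mcfg: ModelConfig | None = None,
    mixcfg: MixupConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, MetricsReport]]:
    """One full LOSOCV per motion-set spec; fold seeds are paired across arms.

    Returns a comparison table (one row per spec) and the full reports.
    """
    pipe_cfg = pipe_cfg or PipelineConfig()
    rows = []
    reports: dict[str, MetricsReport] = {}
    for spec in set_specs:
        results, failures = losocv(cohort, pipe_cfg, mcfg, mixcfg, seed=seed,
                                   motions=spec.motions)
        rep = compute_metrics(results)
        reports[spec.name] = rep
        row = {
            "motion_set": spec.name,
            "n_motions": len(spec.motions),
            "n_folds": len(results),
            "n_failures": len(failures),
            "overall_r2": rep.overall.r2,
            "overall_r": rep.overall.r,
            "overall_nmae": rep.overall.nmae,
            "overall_nrmse": rep.overall.nrmse,
        }
        for part in PART_NAMES:
            row[f"part_{part}_nmae"] = rep.parts[part].nmae
            row[f"part_{part}_nrmse"] = rep.parts[part].nrmse
        rows.append(row)
    return pd.DataFrame(rows).set_index("motion_set"), reports


# ---------------------------------------------------------------------------
# Motion contribution (permutation importance)
# ---------------------------------------------------------------------------

def motion_contribution(
    est: TrainedEstimator,
    tensors: list[FeatureTensor],
    true_scores: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
    motions: tuple[Motion, ...] = MOTIONS,
    permutations: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Permutation-importance contribution of each motion to each part.

    ``tensors`` must be normalized with the estimator's own stats and
    ``true_scores`` given on the normalized [0, 1] scale. For motion m and
    part k, importance is the mean increase in |error_k| when motion m's rows
    are permuted across subjects, averaged over ``n_repeats`` permutations;
    negative increases are floored at zero. Each part's column is normalized
    to sum 1; parts with all-zero raw importance are left unnormalized and
    flagged.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    n = len(tensors)
    y = np.asarray(true_scores, dtype=float)
    x = np.stack([t.values for t in tensors])
    masks = np.stack([t.mask for t in tensors])
    base_pred = est.net.forward(x.astype(np.float32), masks)
    base_err = np.abs(base_pred - y)  # (n, 4)

    rng = np.random.default_rng(seed)
    raw = np.zeros((len(motions), 4))
    for mi in range(len(motions)):
        inc = np.zeros(4)
        for rep in range(n_repeats):
            if permutations is not None:
                perm = np.asarray(permutations[rep])
            else:
                perm = rng.permutation(n)
            xp = x.copy()
            mp = masks.copy()
            xp[:, mi] = x[perm, mi]
            mp[:, mi] = masks[perm, mi]
            pred = est.net.forward(xp.astype(np.float32), mp)
            inc += (np.abs(pred - y) - base_err).mean(axis=0)
        raw[mi] = inc / n_repeats
    raw = np.maximum(raw, 0.0)
    contrib = raw.copy()
    flags: list[str] = []
    for k, part in enumerate(PART_NAMES):
        s = raw[:, k].sum()
        if s > 0:
            contrib[:, k] = raw[:, k] / s
        else:
            flags.append(f"part_{part}: all-zero raw importance, "
                         "left unnormalized")
    return contrib, flags


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(
    results: list[FoldResult],
    metrics: MetricsReport,
    destination: str | Path,
) -> list[Path]:
    """Write metrics JSON/CSV, per-fold predictions CSV and scatter plots.

    Deterministic: re-running on the same inputs overwrites byte-identical
    data files (no timestamps inside).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    jpath = dest / "metrics.json"
    jpath.write_text(json.dumps(metrics.to_dict(), indent=2, sort_keys=True))
    written.append(jpath)

    cpath = dest / "metrics.csv"
    metrics.to_frame().to_csv(cpath)
    written.append(cpath)

    rows = []
    for r in results:
        for i, part in enumerate(PART_NAMES):
            rows.append({
                "subject_id": r.subject_id,
                "part": part,
                "true": r.true[i],
                "predicted": r.predicted[i],
            })
    ppath = dest / "predictions.csv"
    pd.DataFrame(rows).to_csv(ppath, index=False)
    written.append(ppath)

    true = np.stack([r.true for r in results])
    pred = np.stack([r.predicted for r in results])
    fig, axes = plt.subplots(2, 3, figsize=(13, 8))
    panels = [(i, f"Part {p.upper()}", true[:, i], pred[:, i], _DIVISORS[i])
              for i, p in enumerate(PART_NAMES)]
    panels.append((4, "Total", true.sum(axis=1), pred.sum(axis=1), 66.0))
    for ax, (_, title, t, q, hi) in zip(axes.ravel(), panels):
        ax.scatter(t, q, s=25, alpha=0.8)
        ax.plot([0, hi], [0, hi], "k--", lw=1)
        ax.set_xlabel("true score")
        ax.set_ylabel("estimated score")
        ax.set_title(title)
    axes.ravel()[-1].axis("off")
    fig.tight_layout()
    spath = dest / "scatter.png"
    fig.savefig(spath, dpi=120)
    plt.close(fig)
    written.append(spath)
    return written
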