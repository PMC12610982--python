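"""Channel registry and 1530-dimensional window features.

Channel stack (153 channels, fixed registry order)
--------------------------------------------------
Per IMU segment (hand, forearm, upper arm, trunk) there are 18 base channels:

* acceleration x/y/z (g)
* gyro x/y/z (deg/s)
* orientation x/y/z (deg)
* orientation acceleration x/y/z — second difference of orientation × rate²
* angular difference x/y/z — first difference of orientation × rate
* inclination ratio x/y/z — orientation minus the trunk orientation per axis
  (for the trunk itself: orientation minus its neutral-pose orientation)

each paired with its first-difference counterpart (18 + 18 = 36 per segment),
plus 9 joint-angle channels (wrist, elbow, shoulder × 3 axes): 4 × 36 + 9 = 153.

Per window, 10 statistics are computed per channel — mean, std (population),
rms, amplitude ((max-min)/2), max, min, range (max-min), approximate entropy
(m = 2, r = 0.2 σ, self-matches included), median, interquartile range —
giving 153 × 10 = 1530 features, ordered channel-major / statistic-minor.
The feature index ↔ (channel, statistic) map is bijective and versioned.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .preprocessing import JointAngles
from .session import MOTIONS, PART_NAMES, PART_RANGES, SEGMENTS, Motion, MotionTrial, Segment

__all__ = [
    "REGISTRY_VERSION",
    "STAT_NAMES",
    "N_CHANNELS",
    "N_STATS",
    "N_FEATURES",
    "channel_names",
    "feature_names",
    "registry_table",
    "feature_index",
    "feature_meaning",
    "approximate_entropy",
    "build_channels",
    "window_features",
    "FeatureTensor",
    "assemble_tensor",
    "NormStats",
]

REGISTRY_VERSION = "fmaue-153x10-v1"

STAT_NAMES: tuple[str, ...] = (
    "mean", "std", "rms", "amplitude", "max", "min", "range", "apen",
    "median", "iqr",
)

_BASE_FAMILIES: tuple[str, ...] = ("acc", "gyro", "orient", "oacc", "adiff", "incl")
_AXES = ("x", "y", "z")


def channel_names() -> list[str]:
    """The 153 channel names in fixed registry order."""
    names: list[str] = []
    for seg in SEGMENTS:
        base = [f"{seg.value}.{fam}_{ax}" for fam in _BASE_FAMILIES for ax in _AXES]
        names.extend(base)
        names.extend(f"{b}.d1" for b in base)
    for joint in ("wrist", "elbow", "shoulder"):
        names.extend(f"joint.{joint}_{ax}" for ax in _AXES)
    return names


_CHANNEL_NAMES = channel_names()
N_CHANNELS = len(_CHANNEL_NAMES)
N_STATS = len(STAT_NAMES)
N_FEATURES = N_CHANNELS * N_STATS
assert N_CHANNELS == 153 and N_FEATURES == 1530


def feature_names() -> list[str]:
    """All 1530 feature names as 'channel::statistic'."""
    return [f"{c}::{s}" for c in _CHANNEL_NAMES for s in STAT_NAMES]


def feature_index(channel: str, stat: str) -> int:
    """Registry map (channel, statistic) -> feature index."""
    return _CHANNEL_NAMES.index(channel) * N_STATS + STAT_NAMES.index(stat)


def feature_meaning(index: int) -> tuple[str, str]:
    """Registry map feature index -> (channel, statistic)."""
    if not 0 <= index < N_FEATURES:
        raise IndexError(index)
    return _CHANNEL_NAMES[index // N_STATS], STAT_NAMES[index % N_STATS]


def registry_table() -> pd.DataFrame:
    """Two-column feature registry (feature_index, channel::statistic)."""
    return pd.DataFrame(
        {"feature_index": np.arange(N_FEATURES), "name": feature_names()}
    )


# ---------------------------------------------------------------------------
# Approximate entropy
# ---------------------------------------------------------------------------

def approximate_entropy(series: np.ndarray, m: int = 2,
                        r: float | None = None) -> float:
    """Classical approximate entropy ApEn(m, r) = Φ_m(r) − Φ_{m+1}(r).

    Chebyshev distance between embedded templates, self-matches included.
    ``r`` defaults to 0.2 × the population std of the series; a constant
    series (std = 0) returns 0 by convention.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series too short for ApEn (need >= {m + 2})")
    sd = x.std()
    if r is None:
        if sd == 0:
            return 0.0
        r = 0.2 * sd
    if r <= 0:
        raise ValueError("r must be positive")
    return float(_apen_matrix(x[:, None], m, np.array([r]))[0])


def _apen_matrix(X: np.ndarray, m: int, r: np.ndarray) -> np.ndarray:
    """ApEn of each column of (n, C) matrix X with per-column tolerance r.

    Columns with r <= 0 (constant channels) return 0. Exact counting in
    float64: a Chebyshev match within r is the conjunction of per-lag
    |x_i+k − x_j+k| <= r, evaluated on boolean match matrices.
    """
    X = np.asarray(X, dtype=np.float64)
    n, c = X.shape
    r = np.asarray(r, dtype=np.float64)
    out = np.zeros(c)
    live = np.flatnonzero(r > 0)
    if len(live) == 0:
        return out
    for j in live:
        d0 = np.abs(X[:, None, j] - X[None, :, j])
        b = d0 <= r[j]
        bm = b
        for k in range(1, m):
            bm = bm[:-1, :-1] & b[k:, k:]  # embeds one more lag
        c_m = bm.mean(axis=1)
        phi_m = np.log(c_m).mean()
        bm1 = bm[:-1, :-1] & b[m:, m:]
        c_m1 = bm1.mean(axis=1)
        phi_m1 = np.log(c_m1).mean()
        out[j] = phi_m - phi_m1
    return out


# ---------------------------------------------------------------------------
# Channel stack
# ---------------------------------------------------------------------------

def _d1(x: np.ndarray) -> np.ndarray:
    """Forward difference with first-sample replication (length preserved)."""
    d = np.diff(x, axis=0)
    return np.concatenate([d[:1], d], axis=0)


def build_channels(
    trial: MotionTrial,
    angles: JointAngles,
    neutral_index: int = 0,
) -> np.ndarray:
    """Realize the 153-channel stack of a preprocessed trial, (N, 153).

    Derived channels use forward differences with first-sample replication so
    every column keeps the trial length. Inclination ratio references the
    trunk IMU (the trunk's own inclination references its neutral sample).
    """
    if angles is None:
        raise ValueError("joint angles are required to build the channel stack")
    rate = trial.rate
    trunk_orient = trial.recordings[Segment.TRUNK].orient
    cols: list[np.ndarray] = []
    for seg in SEGMENTS:
        rec = trial.recordings[seg]
        orient = rec.orient
        if seg is Segment.TRUNK:
            incl = orient - orient[neutral_index]
        else:
            incl = orient - trunk_orient
        base = np.hstack([
            rec.acc,
            rec.gyro,
            orient,
            _d1(_d1(orient)) * rate**2,  # orientation acceleration
            _d1(orient) * rate,          # angular difference
            incl,
        ])
        cols.append(base)
        cols.append(_d1(base))
    cols.append(angles.stacked())
    out = np.hstack(cols)
    if out.shape[1] != N_CHANNELS:
        raise ValueError(f"channel stack has {out.shape[1]} columns, "
                         f"expected {N_CHANNELS}")
    return out


# ---------------------------------------------------------------------------
# Window features
# ---------------------------------------------------------------------------

def window_features(window: np.ndarray, apen_m: int = 2,
                    apen_r_rel: float = 0.2) -> np.ndarray:
    """Compute the 1530-feature vector of one (win_len, 153) window.

    Ordered channel-major / statistic-minor per the registry. Deterministic.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 2 or w.shape[1] != N_CHANNELS:
        raise ValueError(f"window must be (win_len, {N_CHANNELS})")
    mx = w.max(axis=0)
    mn = w.min(axis=0)
    sd = w.std(axis=0)  # population form
    stats = np.empty((N_CHANNELS, N_STATS))
    stats[:, 0] = w.mean(axis=0)
    stats[:, 1] = sd
    stats[:, 2] = np.sqrt(np.mean(w**2, axis=0))
    stats[:, 3] = (mx - mn) / 2.0
    stats[:, 4] = mx
    stats[:, 5] = mn
    stats[:, 6] = mx - mn
    stats[:, 7] = _apen_matrix(w, apen_m, apen_r_rel * sd)
    stats[:, 8] = np.median(w, axis=0)
    q75, q25 = np.percentile(w, [75, 25], axis=0)
    stats[:, 9] = q75 - q25
    return stats.ravel()


# ---------------------------------------------------------------------------
# Tensor assembly and normalization
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FeatureTensor:
    """Per-subject model input: [7 motions, WL windows, 1530 features].

    ``mask`` marks real (unpadded) window slots; padded slots repeat the last
    real window of their motion.
    """

    values: np.ndarray  # (7, WL, 1530)
    mask: np.ndarray    # (7, WL) bool
    registry_version: str = REGISTRY_VERSION

    @property
    def wl(self) -> int:
        return self.values.shape[1]


def assemble_tensor(
    session_windows: dict[Motion, list[np.ndarray]] | list[list[np.ndarray]],
    wl: int = 9,
    motions: tuple[Motion, ...] = MOTIONS,
) -> FeatureTensor:
    """Pack per-motion feature-vector lists into a [M, WL, 1530] tensor.

    A motion with more than WL windows is cropped centrally; one with fewer
    is padded by repeating its last window (padding recorded in the mask).
    """
    if isinstance(session_windows, dict):
        per_motion = [session_windows[m] for m in motions]
    else:
        per_motion = list(session_windows)
    values = np.empty((len(per_motion), wl, N_FEATURES))
    mask = np.ones((len(per_motion), wl), dtype=bool)
    for i, vecs in enumerate(per_motion):
        if len(vecs) == 0:
            raise ValueError(f"motion {motions[i]} has zero windows")
        arr = np.asarray(vecs, dtype=float)
        n = arr.shape[0]
        if n >= wl:
            start = (n - wl) // 2
            values[i] = arr[start:start + wl]
        else:
            values[i, :n] = arr
            values[i, n:] = arr[-1]
            mask[i, n:] = False
    return FeatureTensor(values=values, mask=mask)


_DIVISORS = np.array([PART_RANGES[p] for p in PART_NAMES], dtype=float)


@dataclasses.dataclass
class NormStats:
    """Feature z-scoring statistics (training folds only) and score divisors."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    divisors: np.ndarray = dataclasses.field(
        default_factory=lambda: _DIVISORS.copy())
    fitted: bool = False

    def fit(self, tensors: list[FeatureTensor]) -> "NormStats":
        """Fit per-feature mean/std on the unpadded windows of training data."""
        rows = np.concatenate(
            [t.values[t.mask] for t in tensors], axis=0)
        self.mean = rows.mean(axis=0)
        self.std = np.maximum(rows.std(axis=0), 1e-8)
        self.fitted = True
        return self

    def transform(self, tensor: FeatureTensor) -> FeatureTensor:
        """Z-score a tensor with training statistics."""
        if not self.fitted:
            raise RuntimeError("NormStats.transform called before fit")
        return FeatureTensor(
            values=(tensor.values - self.mean) / self.std,
            mask=tensor.mask.copy(),
            registry_version=tensor.registry_version,
        )

    def normalize_scores(self, scores: np.ndarray) -> np.ndarray:
        """Map raw sub-scores onto [0, 1] by the part ranges (36, 10, 14, 6)."""
        return np.asarray(scores, dtype=float) / self.divisors

    def denormalize_scores(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) * self.divisors


def fit_norm(tensors: list[FeatureTensor]) -> NormStats:
    """Convenience wrapper: fit a :class:`NormStats` on training tensors."""
    return NormStats().fit(tensors)


def apply_norm(stats: NormStats, tensor: FeatureTensor) -> FeatureTensor:
    """Apply fitted normalization to any tensor (train or test)."""
    return stats.transform(tensor)
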