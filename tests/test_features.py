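"""Feature registry, approximate entropy, window statistics, tensor assembly.

Oracle style: every statistic is checked against an independent brute-force
implementation (explicit loops / textbook formulas) on random windows.
"""

import math

import numpy as np
import pytest

from fmaue.features import (
    N_CHANNELS,
    N_FEATURES,
    N_STATS,
    STAT_NAMES,
    NormStats,
    approximate_entropy,
    assemble_tensor,
    build_channels,
    channel_names,
    feature_index,
    feature_meaning,
    fit_norm,
    window_features,
)
from fmaue.preprocessing import JointAngles
from fmaue.session import Motion, MotionTrial, Segment, SegmentRecording


# ------------------------------------------------------------------- registry

def test_registry_has_153_unique_channels_and_1530_features():
    names = channel_names()
    assert len(names) == N_CHANNELS == 153
    assert len(set(names)) == 153
    assert N_FEATURES == 1530


def test_feature_index_bijection():
    seen = set()
    for i in range(N_FEATURES):
        ch, st = feature_meaning(i)
        assert feature_index(ch, st) == i
        seen.add((ch, st))
    assert len(seen) == N_FEATURES


# ------------------------------------------------------------------- ApEn

def _apen_brute(x, m, r):
    """Independent O(N^2 m) template-counting ApEn (self-matches included)."""
    n = len(x)

    def phi(mm):
        total = 0.0
        for i in range(n - mm + 1):
            c = 0
            for j in range(n - mm + 1):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            total += math.log(c / (n - mm + 1))
        return total / (n - mm + 1)

    return phi(m) - phi(m + 1)


def test_apen_constant_series_is_zero():
    assert approximate_entropy(np.full(50, 2.5)) == 0.0


def test_apen_periodic_series_is_small():
    x = np.tile([1.0, 2.0], 50)
    assert approximate_entropy(x, m=2) < 0.05


def test_apen_matches_brute_force_oracle():
    rng = np.random.default_rng(99)
    x = rng.standard_normal(50)
    r = 0.2 * x.std()
    got = approximate_entropy(x, m=2, r=r)
    want = _apen_brute(x, 2, r)
    assert got == pytest.approx(want, abs=1e-10)


def test_apen_random_more_irregular_than_periodic():
    rng = np.random.default_rng(1)
    periodic = np.tile([0.0, 1.0, 2.0, 1.0], 50)
    noise = rng.standard_normal(200)
    assert approximate_entropy(noise) > approximate_entropy(periodic)


def test_apen_too_short_raises():
    with pytest.raises(ValueError, match="short"):
        approximate_entropy(np.array([1.0, 2.0, 3.0]), m=2)


# ------------------------------------------------------------------- stats

def _stats_brute(col):
    """Textbook formulas, implemented independently of window_features."""
    n = len(col)
    mean = sum(col) / n
    var = sum((v - mean) ** 2 for v in col) / n
    sd = math.sqrt(var)
    rms = math.sqrt(sum(v * v for v in col) / n)
    mx, mn = max(col), min(col)
    srt = sorted(col)
    med = float(np.percentile(col, 50))
    iqr = float(np.percentile(col, 75) - np.percentile(col, 25))
    apen = _apen_brute(list(col), 2, 0.2 * sd) if sd > 0 else 0.0
    return dict(mean=mean, std=sd, rms=rms, amplitude=(mx - mn) / 2, max=mx,
                min=mn, range=mx - mn, apen=apen, median=med, iqr=iqr)


def test_window_features_length_and_layout():
    rng = np.random.default_rng(0)
    w = rng.standard_normal((200, N_CHANNELS))
    f = window_features(w)
    assert f.shape == (1530,)
    # channel-major, statistic-minor: feature c*10 is channel c's mean
    np.testing.assert_allclose(f[::N_STATS], w.mean(axis=0), atol=1e-12)


def test_constant_channel_closed_forms():
    rng = np.random.default_rng(2)
    w = rng.standard_normal((100, N_CHANNELS))
    w[:, 7] = 5.0
    f = window_features(w)[7 * N_STATS:(7 + 1) * N_STATS]
    expected = dict(zip(STAT_NAMES, f))
    assert expected == {
        "mean": 5.0, "std": 0.0, "rms": 5.0, "amplitude": 0.0, "max": 5.0,
        "min": 5.0, "range": 0.0, "apen": 0.0, "median": 5.0, "iqr": 0.0}


def test_ramp_channel_matches_textbook_formulas():
    w = np.zeros((200, N_CHANNELS))
    ramp = np.arange(1, 201) / 200.0
    w[:, 0] = ramp
    f = window_features(w)[:N_STATS]
    want = _stats_brute(list(ramp))
    for i, name in enumerate(STAT_NAMES):
        assert f[i] == pytest.approx(want[name], abs=1e-10), name


def test_all_statistics_match_brute_force_on_random_window():
    rng = np.random.default_rng(31)
    w = rng.standard_normal((200, N_CHANNELS))
    f = window_features(w).reshape(N_CHANNELS, N_STATS)
    # full brute-force check (including O(N^2) ApEn) on a channel sample
    for c in (0, 41, 152):
        want = _stats_brute(list(w[:, c]))
        for i, name in enumerate(STAT_NAMES):
            assert f[c, i] == pytest.approx(want[name], abs=1e-10), \
                (c, name)
    # vectorized-formula check of the nine simple stats on every channel
    np.testing.assert_allclose(f[:, 0], w.mean(axis=0), atol=1e-10)
    np.testing.assert_allclose(f[:, 1], w.std(axis=0), atol=1e-10)
    np.testing.assert_allclose(f[:, 2], np.sqrt((w**2).mean(axis=0)),
                               atol=1e-10)
    np.testing.assert_allclose(f[:, 4], w.max(axis=0), atol=1e-12)
    np.testing.assert_allclose(f[:, 5], w.min(axis=0), atol=1e-12)
    np.testing.assert_allclose(f[:, 6], np.ptp(w, axis=0), atol=1e-12)
    np.testing.assert_allclose(f[:, 3], np.ptp(w, axis=0) / 2, atol=1e-12)
    np.testing.assert_allclose(f[:, 8], np.median(w, axis=0), atol=1e-12)


def test_channel_permutation_permutes_feature_blocks():
    rng = np.random.default_rng(4)
    w = rng.standard_normal((80, N_CHANNELS))
    perm = rng.permutation(N_CHANNELS)
    f = window_features(w).reshape(N_CHANNELS, N_STATS)
    fp = window_features(w[:, perm]).reshape(N_CHANNELS, N_STATS)
    np.testing.assert_allclose(fp, f[perm], atol=1e-12)


def test_wrong_channel_count_rejected():
    with pytest.raises(ValueError, match="153"):
        window_features(np.zeros((50, 10)))


# ------------------------------------------------------------------- channels

def _static_trial(orient_value=15.0, n=50):
    t = np.arange(n) / 100.0
    recs = {
        seg: SegmentRecording(
            segment_id=seg, timestamps=t.copy(),
            acc=np.full((n, 3), 0.3), gyro=np.zeros((n, 3)),
            orient=np.full((n, 3), orient_value), nominal_rate=100.0)
        for seg in Segment
    }
    return MotionTrial(motion=Motion.RU, recordings=recs)


def test_zero_motion_trial_derived_channels_vanish():
    trial = _static_trial()
    n = 50
    angles = JointAngles(wrist=np.zeros((n, 3)), elbow=np.zeros((n, 3)),
                         shoulder=np.zeros((n, 3)))
    chans = build_channels(trial, angles)
    assert chans.shape == (n, 153)
    names = channel_names()
    for i, name in enumerate(names):
        family = name.split(".")[1].split("_")[0] if "." in name else ""
        if name.endswith(".d1") or family in ("oacc", "adiff", "incl") \
                or name.startswith("joint."):
            np.testing.assert_allclose(chans[:, i], 0.0, atol=1e-12,
                                       err_msg=name)


def test_inclination_ratio_zero_when_segment_tracks_trunk(synthetic_session):
    # by construction equal orientations: reuse static trial where all match
    trial = _static_trial()
    angles = JointAngles(*(np.zeros((50, 3)) for _ in range(3)))
    chans = build_channels(trial, angles)
    names = channel_names()
    i = names.index("forearm.incl_x")
    np.testing.assert_allclose(chans[:, i:i + 3], 0.0, atol=1e-12)


def test_missing_angles_rejected(synthetic_session):
    trial = _static_trial()
    with pytest.raises(ValueError, match="angles"):
        build_channels(trial, None)


# ------------------------------------------------------------------- assembly

def _vecs(k, fill=None, rng=None):
    out = []
    for i in range(k):
        if rng is not None:
            out.append(rng.standard_normal(N_FEATURES))
        else:
            v = np.full(N_FEATURES, float(i if fill is None else fill))
            out.append(v)
    return out


def test_exact_fit_is_identity_packing():
    per = [_vecs(9) for _ in range(7)]
    t = assemble_tensor(per, wl=9)
    assert t.values.shape == (7, 9, N_FEATURES)
    assert t.mask.all()
    np.testing.assert_allclose(t.values[0, :, 0], np.arange(9))


def test_overflow_cropped_centrally():
    per = [_vecs(9) for _ in range(7)]
    per[2] = _vecs(13)  # 13 windows -> central 9: indices 2..10
    t = assemble_tensor(per, wl=9)
    np.testing.assert_allclose(t.values[2, :, 0], np.arange(2, 11))
    assert t.mask.all()


def test_underflow_padded_with_last_window_and_masked():
    per = [_vecs(9) for _ in range(7)]
    per[5] = _vecs(7)
    t = assemble_tensor(per, wl=9)
    np.testing.assert_allclose(t.values[5, 7:, 0], 6.0)
    assert (~t.mask[5]).sum() == 2
    assert t.mask[5, :7].all() and not t.mask[5, 7:].any()


def test_zero_windows_rejected():
    per = [_vecs(9) for _ in range(7)]
    per[3] = []
    with pytest.raises(ValueError, match="zero windows"):
        assemble_tensor(per, wl=9)


# ------------------------------------------------------------------- norm

def test_score_normalization_by_part_ranges():
    ns = NormStats()
    np.testing.assert_allclose(ns.normalize_scores([36, 10, 14, 6]),
                               [1, 1, 1, 1])
    np.testing.assert_allclose(ns.normalize_scores([18, 5, 7, 3]),
                               [0.5, 0.5, 0.5, 0.5])
    np.testing.assert_allclose(ns.denormalize_scores([1, 1, 1, 1]),
                               [36, 10, 14, 6])


def test_zscore_property_on_training_data():
    rng = np.random.default_rng(8)
    tensors = [assemble_tensor([_vecs(9, rng=rng) for _ in range(7)], wl=9)
               for _ in range(4)]
    ns = fit_norm(tensors)
    rows = np.concatenate([ns.transform(t).values[t.mask] for t in tensors])
    np.testing.assert_allclose(rows.mean(axis=0), 0.0, atol=1e-8)
    np.testing.assert_allclose(rows.std(axis=0), 1.0, atol=1e-6)


def test_transform_before_fit_raises():
    t = assemble_tensor([_vecs(9) for _ in range(7)], wl=9)
    with pytest.raises(RuntimeError, match="before fit"):
        NormStats().transform(t)
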