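"""End-to-end featurization: raw session -> model input tensor.

Chains the conditioning, joint-angle, channel-stack, windowing and feature
stages into per-subject [M, WL, 1530] tensors, and produces the augmented
variants used for training (and, for a held-out subject, as that subject's
multiple test samples whose predictions are averaged).
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np

from .features import (
    FeatureTensor,
    assemble_tensor,
    build_channels,
    window_features,
)
from .preprocessing import (
    AugmentConfig,
    PreprocessConfig,
    augment_trial,
    compute_joint_angles,
    preprocess_trial,
    window_trial,
)
from .session import MOTIONS, Motion, MotionTrial, SubjectSession

__all__ = ["PipelineConfig", "trial_feature_windows", "session_to_tensor",
           "session_variants", "subject_seed"]


@dataclasses.dataclass
class PipelineConfig:
    """All knobs from raw streams to the model input tensor."""

    preprocess: PreprocessConfig = dataclasses.field(
        default_factory=PreprocessConfig)
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    wl: int = 9  # a 10 s trial at 100 Hz with 2 s / 50% windows gives 9


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Deterministic per-subject seed below 2^31 (master seed + id hash)."""
    h = zlib.crc32(subject_id.encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0]
               % (2**31))


def trial_feature_windows(
    trial: MotionTrial,
    pre_cfg: PreprocessConfig,
    wl: int | None = None,
) -> list[np.ndarray]:
    """Preprocess one trial and return its per-window 1530-feature vectors.

    When ``wl`` is given and the trial yields more windows, the central ``wl``
    windows are selected before feature computation — identical to computing
    all features and cropping centrally afterwards, since features are
    strictly per-window.
    """
    clean = preprocess_trial(trial, pre_cfg)
    angles = compute_joint_angles(clean, pre_cfg.neutral_index)
    chans = build_channels(clean, angles, pre_cfg.neutral_index)
    wt = window_trial(chans, clean.rate, pre_cfg.win_s, pre_cfg.overlap,
                      motion=trial.motion)
    wins = wt.windows
    if wl is not None and len(wins) > wl:
        start = (len(wins) - wl) // 2
        wins = wins[start:start + wl]
    return [window_features(w) for w in wins]


def session_to_tensor(
    session: SubjectSession,
    cfg: PipelineConfig,
    motions: tuple[Motion, ...] = MOTIONS,
) -> FeatureTensor:
    """Featurize a session into its [len(motions), WL, 1530] tensor."""
    per = {m: trial_feature_windows(session.trials[m], cfg.preprocess, cfg.wl)
           for m in motions}
    return assemble_tensor(per, cfg.wl, motions)


def session_variants(
    session: SubjectSession,
    cfg: PipelineConfig,
    seed: int,
    motions: tuple[Motion, ...] = MOTIONS,
) -> list[FeatureTensor]:
    """The original tensor plus ``copies_per_trial`` augmented variants.

    Augmentation seeds derive from (seed, subject id, motion, copy) so the
    variants are stable across evaluation folds and paired across ablation
    arms.
    """
    out = [session_to_tensor(session, cfg, motions)]
    n_copies = cfg.augment.copies_per_trial
    if n_copies == 0:
        return out
    base = subject_seed(seed, session.subject_id)
    aug_by_motion: dict[Motion, list] = {}
    for mi, m in enumerate(motions):
        trial_cfg = dataclasses.replace(cfg.augment)
        copies = augment_trial(
            session.trials[m], trial_cfg,
            seed=np.random.SeedSequence([base, mi]))
        aug_by_motion[m] = copies
    for k in range(n_copies):
        per = {m: trial_feature_windows(aug_by_motion[m][k], cfg.preprocess,
                                        cfg.wl)
               for m in motions}
        out.append(assemble_tensor(per, cfg.wl, motions))
    return out
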