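"""Impairment-graded synthetic IMU cohort generator.

Emulates the study conditions the estimation pipeline assumes: cohorts of
~15 subjects, one assessed arm each, performing the seven specialized motions
(~10 s per trial, ~5 repetitions) with four segment IMUs at 100 Hz, graded by
a latent 4-vector of impairment severities aligned with the four FMA-UE parts
(A shoulder/elbow, B wrist, C hand, D coordination).

The kinematic model is intentionally simple but captures exactly the signal
properties the downstream feature set measures:

* smooth minimum-jerk oscillatory segment-orientation trajectories,
* impairment-dependent range of motion (amplitude shrinks with severity),
* impairment-dependent slowing (repetition period grows with severity),
* band-limited 3-8 Hz tremor whose power grows with severity,
* gravity-consistent accelerometer signals plus white sensor noise.

Each motion couples to the four severity components through a fixed coupling
vector whose dominant entry is the FMA-UE part that motion chiefly probes
(RU/RKE/HTS/EPS -> A, WC -> B, HMFE -> C, RKN -> D). Derived sub-scores are a
deterministic function of severity alone: score_k = round((1 - s_k) * range_k).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .session import (
    MOTIONS,
    PART_NAMES,
    PART_RANGES,
    SEGMENTS,
    FmaSubScores,
    Motion,
    MotionTrial,
    Segment,
    SegmentRecording,
    SubjectSession,
)

__all__ = [
    "ImpairmentProfile",
    "MotionKinematicsSpec",
    "NoiseFloors",
    "CohortConfig",
    "MOTION_SPECS",
    "simulate_trial",
    "simulate_subject",
    "simulate_cohort",
    "sample_severities",
]

_RANGES = np.array([PART_RANGES[p] for p in PART_NAMES], dtype=float)

#: Fraction of range-of-motion lost at full severity.
AMPLITUDE_LOSS = 0.8
#: Tremor band and amplitude scale (degrees of orientation jitter at w·s = 1).
TREMOR_BAND_HZ = (3.0, 8.0)
TREMOR_GAIN_DEG = 2.0
#: Effective lever arm (m) converting angular acceleration to linear acc.
LEVER_ARM_M = 0.25
_G = 9.80665


@dataclasses.dataclass
class NoiseFloors:
    """White sensor-noise standard deviations (consumer-IMU magnitudes)."""

    acc_g: float = 0.01
    gyro_dps: float = 0.5


@dataclasses.dataclass
class ImpairmentProfile:
    """Latent per-part severity in [0, 1]; 0 = unimpaired, 1 = maximal."""

    severity: np.ndarray  # (4,) for parts A, B, C, D

    def __post_init__(self) -> None:
        self.severity = np.asarray(self.severity, dtype=float)
        if self.severity.shape != (4,):
            raise ValueError("severity must be a 4-vector (parts A-D)")
        if np.any(self.severity < 0) or np.any(self.severity > 1):
            raise ValueError("severity components must lie in [0, 1]")

    def derived_scores(self) -> FmaSubScores:
        """Deterministic sub-scores: round((1 - s_k) * range_k), half up."""
        vals = np.floor((1.0 - self.severity) * _RANGES + 0.5).astype(int)
        return FmaSubScores(*(int(v) for v in vals))


@dataclasses.dataclass
class MotionKinematicsSpec:
    """Kinematic template of one specialized motion.

    ``coupling`` weights how the four severity components scale this motion's
    amplitude loss, slowing, and tremor; its dominant entry is the motion's
    FMA-UE target part. ``segment_gains`` distributes the base amplitude over
    segment orientation axes (x transverse, y longitudinal, z anteroposterior).
    """

    motion: Motion
    dominant_part: str  # "a" | "b" | "c" | "d"
    base_amplitude: float  # degrees, at zero severity
    base_period: float  # seconds per repetition, at zero severity
    coupling: np.ndarray  # (4,) non-negative, sums to 1
    segment_gains: dict[Segment, np.ndarray]

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (4,) or np.any(self.coupling < 0):
            raise ValueError("coupling must be a non-negative 4-vector")
        if not np.isclose(self.coupling.sum(), 1.0):
            raise ValueError("coupling weights must sum to 1")
        dom = self.coupling[PART_NAMES.index(self.dominant_part)]
        if np.any(self.coupling > dom + 1e-12):
            raise ValueError("dominant part must carry the largest weight")
        self.segment_gains = {
            s: np.asarray(g, dtype=float) for s, g in self.segment_gains.items()
        }

    def weighted_severity(self, profile: ImpairmentProfile) -> float:
        return float(self.coupling @ profile.severity)


def _gains(hand=(0, 0, 0), forearm=(0, 0, 0), upper_arm=(0, 0, 0),
           trunk=(0, 0, 0)) -> dict[Segment, np.ndarray]:
    return {
        Segment.HAND: np.array(hand, dtype=float),
        Segment.FOREARM: np.array(forearm, dtype=float),
        Segment.UPPER_ARM: np.array(upper_arm, dtype=float),
        Segment.TRUNK: np.array(trunk, dtype=float),
    }


#: Default kinematic templates for the seven motions. Coupling defaults:
#: dominant part 0.7 with the remainder on the other parts the motion touches
#: (1.0 when it touches only its dominant part).
MOTION_SPECS: dict[Motion, MotionKinematicsSpec] = {
    Motion.RU: MotionKinematicsSpec(
        Motion.RU, "a", base_amplitude=100.0, base_period=2.0,
        coupling=[1.0, 0.0, 0.0, 0.0],
        segment_gains=_gains(hand=(0.7, 0.1, 0.1), forearm=(0.85, 0.1, 0.1),
                             upper_arm=(1.0, 0.15, 0.1), trunk=(0.06, 0, 0.04)),
    ),
    Motion.RKE: MotionKinematicsSpec(
        Motion.RKE, "a", base_amplitude=85.0, base_period=2.2,
        coupling=[1.0, 0.0, 0.0, 0.0],
        segment_gains=_gains(hand=(0.5, 0.2, 0.3), forearm=(0.65, 0.3, 0.25),
                             upper_arm=(0.8, 0.2, 0.5), trunk=(0.05, 0, 0.05)),
    ),
    Motion.HTS: MotionKinematicsSpec(
        Motion.HTS, "a", base_amplitude=60.0, base_period=2.0,
        coupling=[1.0, 0.0, 0.0, 0.0],
        segment_gains=_gains(hand=(0.4, 0.3, 0.2), forearm=(0.55, 0.35, 0.2),
                             upper_arm=(0.5, 0.2, 0.7), trunk=(0.05, 0, 0.03)),
    ),
    Motion.EPS: MotionKinematicsSpec(
        Motion.EPS, "a", base_amplitude=80.0, base_period=1.8,
        coupling=[1.0, 0.0, 0.0, 0.0],
        segment_gains=_gains(hand=(0.1, 1.0, 0.05), forearm=(0.1, 1.0, 0.05),
                             upper_arm=(0.03, 0.08, 0.02), trunk=(0.01, 0, 0.01)),
    ),
    Motion.WC: MotionKinematicsSpec(
        Motion.WC, "b", base_amplitude=50.0, base_period=1.8,
        coupling=[0.3, 0.7, 0.0, 0.0],
        segment_gains=_gains(hand=(1.0, 0.2, 0.6), forearm=(0.1, 0.05, 0.05),
                             upper_arm=(0.02, 0.01, 0.01), trunk=(0.01, 0, 0.01)),
    ),
    Motion.HMFE: MotionKinematicsSpec(
        Motion.HMFE, "c", base_amplitude=45.0, base_period=1.6,
        coupling=[0.0, 0.0, 1.0, 0.0],
        segment_gains=_gains(hand=(1.0, 0.05, 0.1), forearm=(0.06, 0.02, 0.02),
                             upper_arm=(0.01, 0.01, 0.01), trunk=(0.005, 0, 0.005)),
    ),
    Motion.RKN: MotionKinematicsSpec(
        Motion.RKN, "d", base_amplitude=90.0, base_period=2.0,
        coupling=[0.3, 0.0, 0.0, 0.7],
        segment_gains=_gains(hand=(0.6, 0.15, 0.2), forearm=(0.8, 0.2, 0.2),
                             upper_arm=(0.9, 0.15, 0.4), trunk=(0.05, 0, 0.04)),
    ),
}


def _min_jerk_cycle(tau: np.ndarray) -> np.ndarray:
    """One out-and-back repetition on phase in [0,1): min-jerk 0->1->0."""
    u = np.where(tau < 0.5, 2.0 * tau, 2.0 - 2.0 * tau)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _band_noise(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-std band-limited (3-8 Hz) noise of length n."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, TREMOR_BAND_HZ, btype="bandpass", fs=rate,
                        output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_trial(
    spec: MotionKinematicsSpec,
    profile: ImpairmentProfile,
    rate: float = 100.0,
    seed: int | np.random.SeedSequence = 0,
    n_reps: int = 5,
    noise: NoiseFloors | None = None,
    tremor_gain_deg: float = TREMOR_GAIN_DEG,
) -> MotionTrial:
    """Simulate one motion trial; deterministic given (spec, profile, seed).

    Effective amplitude = base * (1 - 0.8 * w·s); repetition period =
    base_period * (1 + w·s); tremor std proportional to w·s. Gyro is the time
    derivative of orientation; acceleration combines the gravity component in
    the (rotated) sensor frame, a lever-arm movement term, and white noise.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    noise = noise or NoiseFloors()
    ws = spec.weighted_severity(profile)
    amp = spec.base_amplitude * (1.0 - AMPLITUDE_LOSS * ws)
    period = spec.base_period * (1.0 + ws)
    duration = n_reps * period
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    tau = (t / period) % 1.0
    base = _min_jerk_cycle(tau)

    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    recordings: dict[Segment, SegmentRecording] = {}
    for seg in SEGMENTS:
        gains = spec.segment_gains[seg]
        orient = np.outer(base, gains * amp)  # (n, 3) degrees
        sigma = tremor_gain_deg * ws * float(np.max(gains))
        if sigma > 0:
            for ax in range(3):
                if gains[ax] > 0:
                    orient[:, ax] += sigma * _band_noise(n, rate, rng)
                else:
                    rng.standard_normal(n)  # keep draw order stable
        else:
            rng.standard_normal(3 * n)  # keep draw order stable

        gyro = np.gradient(orient, 1.0 / rate, axis=0)
        gyro += noise.gyro_dps * rng.standard_normal((n, 3))

        rot = Rotation.from_euler("ZYX", orient[:, ::-1], degrees=True)
        grav = rot.inv().apply(np.array([0.0, 0.0, 1.0]))  # g in sensor frame
        ang_acc = np.gradient(np.deg2rad(gyro), 1.0 / rate, axis=0)
        lin = LEVER_ARM_M * ang_acc / _G
        acc = grav + lin + noise.acc_g * rng.standard_normal((n, 3))

        recordings[seg] = SegmentRecording(
            segment_id=seg,
            timestamps=t.copy(),
            acc=np.clip(acc, -8.0, 8.0),
            gyro=np.clip(gyro, -2000.0, 2000.0),
            orient=orient,
            nominal_rate=rate,
        )
    return MotionTrial(motion=spec.motion, recordings=recordings,
                       repetitions=n_reps)


def simulate_subject(
    profile: ImpairmentProfile,
    rate: float = 100.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "S00",
    tested_side: str = "right",
    specs: dict[Motion, MotionKinematicsSpec] | None = None,
    noise: NoiseFloors | None = None,
) -> SubjectSession:
    """Simulate all seven motion trials of one subject."""
    specs = specs or MOTION_SPECS
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(len(MOTIONS))
    trials = {
        m: simulate_trial(specs[m], profile, rate=rate, seed=children[i],
                          noise=noise)
        for i, m in enumerate(MOTIONS)
    }
    return SubjectSession(
        subject_id=subject_id,
        tested_side=tested_side,
        trials=trials,
        scores=profile.derived_scores(),
        is_synthetic=True,
    )


def sample_severities(
    n: int,
    rng: np.random.Generator,
    unimpaired_prob: float = 0.2,
    beta_a: float = 2.0,
    beta_b: float = 2.0,
) -> np.ndarray:
    """Default severity sampler: per-part Beta(2,2) with a 20% chance of an
    entirely unimpaired subject (mirroring 4 healthy of 15 in the cohort the
    generator emulates)."""
    out = np.empty((n, 4))
    for i in range(n):
        if rng.random() < unimpaired_prob:
            out[i] = 0.0
        else:
            out[i] = rng.beta(beta_a, beta_b, size=4)
    return out


@dataclasses.dataclass
class CohortConfig:
    """Configuration of a synthetic cohort."""

    n: int = 15
    seed: int = 0
    rate_hz: float = 100.0
    unimpaired_prob: float = 0.2
    beta_a: float = 2.0
    beta_b: float = 2.0
    noise: NoiseFloors = dataclasses.field(default_factory=NoiseFloors)


def simulate_cohort(
    n: int,
    seed: int = 0,
    rate: float = 100.0,
    severity_sampler: Callable[[int, np.random.Generator], np.ndarray] | None = None,
    noise: NoiseFloors | None = None,
) -> list[SubjectSession]:
    """Simulate a cohort of n independent subjects (n >= 2 for LOSOCV)."""
    if n < 2:
        raise ValueError("cohort size must be >= 2 (LOSOCV needs >= 2)")
    ss = np.random.SeedSequence(seed)
    sev_ss, subj_ss = ss.spawn(2)
    rng = np.random.default_rng(sev_ss)
    if severity_sampler is None:
        severities = sample_severities(n, rng)
    else:
        severities = np.asarray(severity_sampler(n, rng), dtype=float)
    sides = rng.choice(["left", "right"], size=n)
    children = subj_ss.spawn(n)
    sessions = []
    for i in range(n):
        profile = ImpairmentProfile(severities[i])
        sessions.append(
            simulate_subject(
                profile, rate=rate, seed=children[i],
                subject_id=f"S{i + 1:02d}", tested_side=str(sides[i]),
                noise=noise,
            )
        )
    return sessions


def cohort_from_config(cfg: CohortConfig) -> list[SubjectSession]:
    """Simulate a cohort from a :class:`CohortConfig`."""
    def sampler(n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_severities(n, rng, cfg.unimpaired_prob, cfg.beta_a,
                                 cfg.beta_b)

    return simulate_cohort(cfg.n, seed=cfg.seed, rate=cfg.rate_hz,
                           severity_sampler=sampler, noise=cfg.noise)
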