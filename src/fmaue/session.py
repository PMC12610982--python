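"""Domain model for wearable-IMU assessment sessions.

A *session* is one assessed arm of one subject: seven specialized upper-limb
motion trials, each recorded by four body-worn IMUs (hand, forearm, upper arm,
trunk), together with the therapist-rated Fugl-Meyer Assessment Upper-Extremity
(FMA-UE) sub-scores that the estimator learns to predict.

Units are standardized at the I/O boundary: acceleration in g, angular rate in
degrees/second, orientation as three Euler-style angles in degrees (x =
transverse, y = longitudinal, z = anteroposterior axis of the segment). All
downstream math assumes these units.

On disk a session is a directory with one CSV per (motion, segment) pair and a
JSON manifest holding subject metadata and the sub-scores. The layout is
deliberately plain-text so fixtures are human-inspectable and diff-able.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Segment",
    "Motion",
    "PART_NAMES",
    "PART_RANGES",
    "EULER_SEQ",
    "SegmentRecording",
    "MotionTrial",
    "FmaSubScores",
    "SubjectSession",
    "Violation",
    "SessionValidationError",
    "IncompleteSessionError",
    "validate_session",
    "write_session",
    "read_session",
]

# Sensor full-scale ranges of the recording hardware.
ACC_RANGE_G = 8.0
GYRO_RANGE_DPS = 2000.0

#: Intrinsic Euler sequence used everywhere orientation angles meet rotations.
#: Angles (ox, oy, oz) map to a rotation R = Rz(oz) @ Ry(oy) @ Rx(ox).
EULER_SEQ = "ZYX"


class Segment(str, enum.Enum):
    """Body segment an IMU is attached to."""

    HAND = "hand"
    FOREARM = "forearm"
    UPPER_ARM = "upper_arm"
    TRUNK = "trunk"


class Motion(str, enum.Enum):
    """The seven specialized motions, in fixed model-input order."""

    RU = "RU"  # reaching upward
    RKE = "RKE"  # reaching contralateral knee to ipsilateral ear
    HTS = "HTS"  # hand to lumbar spine
    EPS = "EPS"  # elbow pronation-supination
    WC = "WC"  # wrist circumduction
    HMFE = "HMFE"  # hand mass flexion and extension
    RKN = "RKN"  # reaching knee to nose


SEGMENTS: tuple[Segment, ...] = (
    Segment.HAND,
    Segment.FOREARM,
    Segment.UPPER_ARM,
    Segment.TRUNK,
)
MOTIONS: tuple[Motion, ...] = tuple(Motion)

PART_NAMES: tuple[str, ...] = ("a", "b", "c", "d")
#: Full score range of each FMA-UE part: A shoulder/elbow, B wrist, C hand,
#: D coordination/speed. Total <= 66.
PART_RANGES: dict[str, int] = {"a": 36, "b": 10, "c": 14, "d": 6}

_CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "ox", "oy", "oz"]
_QUAT_COLUMNS = ["qw", "qx", "qy", "qz"]


@dataclasses.dataclass
class SegmentRecording:
    """Synchronized acc/gyro/orientation streams of one IMU for one trial.

    Parameters
    ----------
    segment_id : Segment
    timestamps : (N,) seconds, strictly increasing
    acc : (N, 3) acceleration in g
    gyro : (N, 3) angular rate in degrees/second
    orient : (N, 3) orientation angles in degrees
    nominal_rate : nominal sampling rate in Hz
    """

    segment_id: Segment
    timestamps: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    orient: np.ndarray
    nominal_rate: float = 100.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.orient = np.asarray(self.orient, dtype=float)

    def __len__(self) -> int:
        return len(self.timestamps)

    def rotations(self) -> Rotation:
        """Orientation stream as scipy Rotations (intrinsic Z-Y-X)."""
        zyx = self.orient[:, ::-1]  # (oz, oy, ox)
        return Rotation.from_euler(EULER_SEQ, zyx, degrees=True)


@dataclasses.dataclass
class MotionTrial:
    """One motion trial: four segment recordings plus the repetition count."""

    motion: Motion
    recordings: dict[Segment, SegmentRecording]
    repetitions: int = 5

    def __getitem__(self, seg: Segment) -> SegmentRecording:
        return self.recordings[seg]

    @property
    def rate(self) -> float:
        return next(iter(self.recordings.values())).nominal_rate


@dataclasses.dataclass
class FmaSubScores:
    """Integer FMA-UE sub-scores: A 0-36, B 0-10, C 0-14, D 0-6."""

    part_a: int
    part_b: int
    part_c: int
    part_d: int

    @property
    def total(self) -> int:
        return self.part_a + self.part_b + self.part_c + self.part_d

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.part_a, self.part_b, self.part_c, self.part_d], dtype=float
        )

    def to_dict(self) -> dict[str, int]:
        return {
            "a": int(self.part_a),
            "b": int(self.part_b),
            "c": int(self.part_c),
            "d": int(self.part_d),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FmaSubScores":
        return cls(int(d["a"]), int(d["b"]), int(d["c"]), int(d["d"]))


@dataclasses.dataclass
class SubjectSession:
    """All seven motion trials and the true sub-scores for one subject/side."""

    subject_id: str
    tested_side: str  # "left" | "right"
    trials: dict[Motion, MotionTrial]
    scores: FmaSubScores
    is_synthetic: bool = False

    @property
    def rate(self) -> float:
        return next(iter(self.trials.values())).rate


@dataclasses.dataclass
class Violation:
    """One invariant violation found by :func:`validate_session`."""

    kind: str
    field: str
    index: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}/{self.field}: {self.message}"


class SessionValidationError(ValueError):
    """Raised when a session fails validation at an I/O boundary."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


class IncompleteSessionError(FileNotFoundError):
    """An on-disk session is missing one or more (motion, segment) tables."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__("incomplete session: " + ", ".join(missing))


def _validate_recording(rec: SegmentRecording, where: str) -> list[Violation]:
    out: list[Violation] = []
    n = len(rec.timestamps)
    for name, arr, ncol in (
        ("timestamps", rec.timestamps, 1),
        ("acc", rec.acc, 3),
        ("gyro", rec.gyro, 3),
        ("orient", rec.orient, 3),
    ):
        arr = np.atleast_1d(arr)
        if arr.shape[0] != n:
            out.append(
                Violation("length", f"{where}.{name}", None,
                          f"stream length {arr.shape[0]} != {n}")
            )
        if ncol == 3 and (arr.ndim != 2 or arr.shape[1] != 3):
            out.append(
                Violation("shape", f"{where}.{name}", None,
                          f"expected (N, 3), got {arr.shape}")
            )
    if n < 2:
        out.append(Violation("length", f"{where}.timestamps", None,
                             f"stream too short ({n} < 2)"))
    else:
        dt = np.diff(rec.timestamps)
        bad = np.flatnonzero(dt <= 0)
        for i in bad:
            out.append(
                Violation("monotonicity", f"{where}.timestamps", int(i),
                          f"timestamps not strictly increasing at index {i}")
            )
    if rec.acc.ndim == 2 and rec.acc.shape[1] == 3 and len(rec.acc):
        if np.nanmax(np.abs(rec.acc)) > ACC_RANGE_G + 1e-9:
            i = int(np.nanargmax(np.abs(rec.acc).max(axis=1)))
            out.append(Violation("range", f"{where}.acc", i,
                                 f"|acc| exceeds ±{ACC_RANGE_G} g"))
    if rec.gyro.ndim == 2 and rec.gyro.shape[1] == 3 and len(rec.gyro):
        if np.nanmax(np.abs(rec.gyro)) > GYRO_RANGE_DPS + 1e-9:
            i = int(np.nanargmax(np.abs(rec.gyro).max(axis=1)))
            out.append(Violation("range", f"{where}.gyro", i,
                                 f"|gyro| exceeds ±{GYRO_RANGE_DPS} deg/s"))
    return out


def validate_session(session: SubjectSession) -> list[Violation]:
    """Check every session invariant; return a list of violations.

    Total by design: reports problems instead of raising, so it can be used
    both as a gate (empty list == valid) and as a diagnostic.
    """
    out: list[Violation] = []
    try:
        sc = session.scores
        for part in PART_NAMES:
            v = getattr(sc, f"part_{part}")
            hi = PART_RANGES[part]
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= hi):
                out.append(Violation("score", f"part_{part}", None,
                                     f"part_{part} out of range [0,{hi}]"))
        if session.tested_side not in ("left", "right"):
            out.append(Violation("field", "tested_side", None,
                                 f"unknown side {session.tested_side!r}"))
        seen = set(session.trials)
        for m in MOTIONS:
            if m not in seen:
                out.append(Violation("structure", "trials", None,
                                     f"missing motion {m.value}"))
        rates = set()
        for m, trial in session.trials.items():
            segs = set(trial.recordings)
            for s in SEGMENTS:
                if s not in segs:
                    out.append(Violation("structure", f"{m.value}.recordings",
                                         None, f"missing segment {s.value}"))
            for s, rec in trial.recordings.items():
                out.extend(_validate_recording(rec, f"{m.value}.{s.value}"))
                rates.add(rec.nominal_rate)
            # All recordings of one trial must cover the same span (within
            # one sample period).
            spans = [
                (rec.timestamps[0], rec.timestamps[-1])
                for rec in trial.recordings.values()
                if len(rec.timestamps) >= 2
            ]
            if spans:
                tol = 1.0 / trial.rate
                t0s, t1s = zip(*spans)
                if max(t0s) - min(t0s) > tol or max(t1s) - min(t1s) > tol:
                    out.append(Violation("sync", f"{m.value}.recordings", None,
                                         "segment time spans differ by more "
                                         "than one sample period"))
        if len(rates) > 1:
            out.append(Violation("structure", "nominal_rate", None,
                                 f"mixed nominal rates {sorted(rates)}"))
    except Exception as exc:  # noqa: BLE001 - validation must never raise
        out.append(Violation("internal", "session", None,
                             f"validation could not complete: {exc!r}"))
    return out


def _rec_to_frame(rec: SegmentRecording) -> pd.DataFrame:
    data = np.column_stack([rec.timestamps, rec.acc, rec.gyro, rec.orient])
    return pd.DataFrame(data, columns=_CSV_COLUMNS)


def write_session(session: SubjectSession, path: str | Path) -> Path:
    """Write a session directory (28 CSVs + manifest.json); return manifest path.

    Refuses to write a session that fails :func:`validate_session`.
    """
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for motion, trial in session.trials.items():
        for seg, rec in trial.recordings.items():
            fname = root / f"{motion.value}_{seg.value}.csv"
            _rec_to_frame(rec).to_csv(fname, index=False, float_format="%.17g")
    manifest = {
        "subject_id": session.subject_id,
        "tested_side": session.tested_side,
        "scores": session.scores.to_dict(),
        "sample_rate_hz": session.rate,
        "is_synthetic": bool(session.is_synthetic),
        "repetitions": {m.value: t.repetitions for m, t in session.trials.items()},
    }
    mpath = root / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def _frame_to_rec(df: pd.DataFrame, seg: Segment, rate: float) -> SegmentRecording:
    if all(c in df.columns for c in _QUAT_COLUMNS):
        # Optional quaternion orientation (w, x, y, z): convert to the
        # canonical Euler-angle representation on read.
        quat = df[_QUAT_COLUMNS].to_numpy(dtype=float)
        rot = Rotation.from_quat(quat[:, [1, 2, 3, 0]])  # scipy wants (x,y,z,w)
        zyx = rot.as_euler(EULER_SEQ, degrees=True)
        orient = zyx[:, ::-1]
    else:
        orient = df[["ox", "oy", "oz"]].to_numpy(dtype=float)
    return SegmentRecording(
        segment_id=seg,
        timestamps=df["t"].to_numpy(dtype=float),
        acc=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        orient=orient,
        nominal_rate=rate,
    )


def read_session(path: str | Path) -> SubjectSession:
    """Read and validate a session directory written by :func:`write_session`."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise IncompleteSessionError(["manifest.json"])
    manifest = json.loads(mpath.read_text())
    rate = float(manifest.get("sample_rate_hz", 100.0))
    reps = manifest.get("repetitions", {})

    missing: list[str] = []
    trials: dict[Motion, MotionTrial] = {}
    for motion in MOTIONS:
        recs: dict[Segment, SegmentRecording] = {}
        motion_missing = []
        for seg in SEGMENTS:
            fname = root / f"{motion.value}_{seg.value}.csv"
            if not fname.exists():
                motion_missing.append(seg)
                continue
            df = pd.read_csv(fname)
            recs[seg] = _frame_to_rec(df, seg, rate)
        if motion_missing:
            if len(motion_missing) == len(SEGMENTS):
                missing.append(motion.value)
            else:
                missing.extend(
                    f"{motion.value}/{s.value}" for s in motion_missing
                )
            continue
        trials[motion] = MotionTrial(
            motion=motion,
            recordings=recs,
            repetitions=int(reps.get(motion.value, 5)),
        )
    if missing:
        raise IncompleteSessionError(missing)

    session = SubjectSession(
        subject_id=str(manifest["subject_id"]),
        tested_side=str(manifest["tested_side"]),
        trials=trials,
        scores=FmaSubScores.from_dict(manifest["scores"]),
        is_synthetic=bool(manifest.get("is_synthetic", False)),
    )
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    return session
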