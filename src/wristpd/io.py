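"""On-disk trial format and core containers.

A *trial* is one weekly session of the 8-exercise wrist-accelerometer
protocol: a continuous 50 Hz triaxial recording with per-sample activity
labels, plus the clinical scores assigned to the scored exercises.

Layout on disk (one directory per trial):

    <trial_dir>/samples.csv   columns: t, ax, ay, az, label
    <trial_dir>/trial.json    keys: subject_id, group, week, scores

A cohort directory holds one sub-directory per trial plus ``manifest.json``
listing them.

Label taxonomy (integer codes):

    0      postural transition between tasks
    1      resting interval / rest-tremor exercise (the two are merged:
           both are relaxed sitting with the hands supported)
    2..8   exercises 2-8 of the protocol (postural tremor, hand-to-chest,
           finger tapping, hand open-close, pronation-supination,
           sit-to-stand, gait)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: MDS-UPDRS part III items scored in this protocol.
SCORED_ITEMS = ("3.17", "3.15", "3.4", "3.5", "3.6", "3.10")

VALID_LABELS = frozenset(range(9))
VALID_GROUPS = frozenset({"remote", "supervised", "control"})


class FormatError(ValueError):
    """Raised when an on-disk file is structurally malformed."""


class ValidationError(ValueError):
    """Raised when a structurally valid file violates a domain constraint."""


@dataclass
class TriaxialSignal:
    """Uniformly sampled triaxial acceleration in m/s^2 (gravity included)."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValidationError("axis arrays must all match the time grid length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def axes(self) -> np.ndarray:
        """(n, 3) array view of the three axes."""
        return np.column_stack([self.ax, self.ay, self.az])

    def slice(self, start: int, end: int) -> "TriaxialSignal":
        return TriaxialSignal(
            t=self.t[start:end],
            ax=self.ax[start:end],
            ay=self.ay[start:end],
            az=self.az[start:end],
            sampling_rate_hz=self.sampling_rate_hz,
        )


@dataclass(frozen=True)
class LabeledSegment:
    """Contiguous half-open sample range [start, end) with one label code."""

    label_code: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label_code not in VALID_LABELS:
            raise ValidationError(f"unknown label code {self.label_code}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"segment bounds must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class TrialRecord:
    """One weekly session: signal + label segments + clinical scores."""

    subject_id: str
    group: str
    week: int
    signal: TriaxialSignal
    segments: list[LabeledSegment]
    scores: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(f"group must be one of {sorted(VALID_GROUPS)}")
        for item, score in self.scores.items():
            if item not in SCORED_ITEMS:
                raise ValidationError(f"unknown clinical item {item!r}")
            if not (isinstance(score, (int, np.integer)) and 0 <= score <= 4):
                raise ValidationError(
                    f"score for item {item} must be an integer in 0-4, got {score!r}"
                )
        self._check_segments()

    def _check_segments(self) -> None:
        n = len(self.signal)
        prev_end = 0
        for seg in sorted(self.segments, key=lambda s: s.start):
            if seg.start < prev_end:
                raise ValidationError("segments overlap")
            if seg.end > n:
                raise ValidationError("segment extends past the signal")
            prev_end = seg.end
        from collections import Counter

        counts = Counter(s.label_code for s in self.segments)
        for code in range(2, 9):
            if counts.get(code, 0) > 1:
                raise ValidationError(f"exercise label {code} appears more than once")

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}_w{self.week}"

    def labels(self) -> np.ndarray:
        """Per-sample label array reconstructed from the segments."""
        out = np.zeros(len(self.signal), dtype=int)
        for seg in self.segments:
            out[seg.start : seg.end] = seg.label_code
        return out


def segments_from_labels(labels: np.ndarray) -> list[LabeledSegment]:
    """Run-length encode a per-sample label stream into segments."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [LabeledSegment(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def resample_uniform(signal: TriaxialSignal, target_rate_hz: float) -> TriaxialSignal:
    """Linearly interpolate an (possibly irregular) signal onto a uniform grid.

    The output grid starts at ``t[0]`` and steps by ``1/target_rate_hz``; the
    recording duration is preserved to within one sample period.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    t = signal.t
    if len(t) < 2:
        raise ValueError("need at least 2 samples to resample")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing (no duplicates)")
    span = t[-1] - t[0]
    n_out = int(np.floor(span * target_rate_hz)) + 1
    if n_out < 2:
        raise ValueError(
            f"signal spans {span:.4f} s, shorter than 2 samples at {target_rate_hz} Hz"
        )
    grid = t[0] + np.arange(n_out) / target_rate_hz
    return TriaxialSignal(
        t=grid,
        ax=np.interp(grid, t, signal.ax),
        ay=np.interp(grid, t, signal.ay),
        az=np.interp(grid, t, signal.az),
        sampling_rate_hz=float(target_rate_hz),
    )


def write_trial(trial: TrialRecord, path: str | Path) -> None:
    """Write ``samples.csv`` and ``trial.json`` so that read_trial inverts it."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "t": trial.signal.t,
            "ax": trial.signal.ax,
            "ay": trial.signal.ay,
            "az": trial.signal.az,
            "label": trial.labels(),
        }
    )
    # repr-round-trip float formatting keeps read(write(x)) exact
    df.to_csv(path / "samples.csv", index=False, float_format="%.17g", lineterminator="\n")
    meta = {
        "subject_id": trial.subject_id,
        "group": trial.group,
        "week": trial.week,
        "scores": trial.scores,
        "sampling_rate_hz": trial.signal.sampling_rate_hz,
    }
    (path / "trial.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_trial(path: str | Path) -> TrialRecord:
    """Read one trial directory into a validated TrialRecord.

    Rows with non-finite acceleration values are dropped (counted as
    malformed); contiguous runs of equal label become LabeledSegments.
    """
    path = Path(path)
    csv_path = path / "samples.csv"
    json_path = path / "trial.json"
    if not csv_path.exists() or not json_path.exists():
        raise FormatError(f"{path} must contain samples.csv and trial.json")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    required = {"t", "ax", "ay", "az", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"samples.csv missing columns: {sorted(missing)}")
    finite = np.isfinite(df[["t", "ax", "ay", "az"]].to_numpy()).all(axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        df = df.loc[finite].reset_index(drop=True)
    t = df["t"].to_numpy(dtype=float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise FormatError("non-monotone timestamps in samples.csv")
    labels = df["label"].to_numpy(dtype=int)
    bad_labels = set(np.unique(labels)) - VALID_LABELS
    if bad_labels:
        raise ValidationError(f"unknown label codes: {sorted(bad_labels)}")

    meta = json.loads(json_path.read_text())
    rate = float(meta.get("sampling_rate_hz", _infer_rate(t)))
    signal = TriaxialSignal(
        t=t,
        ax=df["ax"].to_numpy(dtype=float),
        ay=df["ay"].to_numpy(dtype=float),
        az=df["az"].to_numpy(dtype=float),
        sampling_rate_hz=rate,
    )
    scores = {str(k): int(v) for k, v in (meta.get("scores") or {}).items()}
    trial = TrialRecord(
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
        week=int(meta["week"]),
        signal=signal,
        segments=segments_from_labels(labels),
        scores=scores,
    )
    trial.n_malformed_rows = n_bad  # type: ignore[attr-defined]
    return trial


def _infer_rate(t: np.ndarray) -> float:
    if len(t) < 2:
        return 50.0
    return 1.0 / float(np.median(np.diff(t)))


def report_gaps(t: np.ndarray, rate_hz: float, max_missing: int = 3) -> list[tuple[int, float]]:
    """Find gaps longer than ``max_missing`` sample periods.

    Returns (index before gap, gap duration in s). Such gaps are reported,
    never silently interpolated, because infill would bias band powers.
    """
    dt = np.diff(np.asarray(t, dtype=float))
    thresh = (max_missing + 1) / rate_hz
    idx = np.flatnonzero(dt > thresh)
    return [(int(i), float(dt[i])) for i in idx]


def write_cohort_manifest(root: str | Path, trial_dirs: list[str]) -> None:
    root = Path(root)
    (root / "manifest.json").write_text(
        json.dumps({"trials": sorted(trial_dirs)}, indent=1) + "\n"
    )


def read_cohort(root: str | Path) -> list[TrialRecord]:
    """Read every trial listed in a cohort manifest."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    return [read_trial(root / d) for d in manifest["trials"]]


def validate_trial_dir(path: str | Path) -> list[str]:
    """Validate one trial directory; returns a list of problems (empty = ok)."""
    problems: list[str] = []
    try:
        trial = read_trial(path)
    except (FormatError, ValidationError, KeyError, OSError) as exc:
        return [f"{path}: {exc}"]
    n_bad = getattr(trial, "n_malformed_rows", 0)
    if n_bad:
        problems.append(f"{path}: {n_bad} malformed sample rows dropped")
    gaps = report_gaps(trial.signal.t, trial.signal.sampling_rate_hz)
    for i, dur in gaps:
        problems.append(f"{path}: gap of {dur:.3f} s after sample {i}")
    return problems
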