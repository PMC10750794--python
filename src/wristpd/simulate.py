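"""Synthetic cohorts of wrist-accelerometer PD motor-exercise sessions.

The simulator emulates the structure of a weekly 8-exercise assessment
recorded by a wrist-worn triaxial accelerometer at 50 Hz:

* gravity as a constant 9.81 m/s^2 offset along a configurable vector;
* severity-linked rest tremor: an amplitude-modulated sinusoid in the
  3.5-7.5 Hz band with a bounded random-walk frequency jitter (+-0.25 Hz),
  injected during resting intervals (rest-tremor score) and the postural
  hold (postural-tremor score), with amplitude a monotone map of the
  0-4 clinical score that is exactly zero at score 0;
* severity-linked bradykinesia: the pronation-supination exercise is a
  sinusoidal rotation-induced acceleration whose cycle rate and amplitude
  both decrease monotonically with the item-3.6 score;
* simple parametric oscillation/burst templates for the remaining
  voluntary movements (hand-to-chest reaches, finger tapping, hand
  open-close, sit-to-stand, gait);
* white sensor noise per axis;
* per-sample labels following the session taxonomy, plus paired
  MDS-UPDRS-like item scores and a ground-truth record for recovery tests.

All randomness flows from a single integer seed; identical seed + config
give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    SCORED_ITEMS,
    TriaxialSignal,
    TrialRecord,
    segments_from_labels,
    write_cohort_manifest,
    write_trial,
)

#: Exercise -> scored MDS-UPDRS item (exercises 3 and 7 are unscored).
EXERCISE_ITEMS = {1: "3.17", 2: "3.15", 4: "3.4", 5: "3.5", 6: "3.6", 8: "3.10"}


def _default_durations() -> dict[int, float]:
    # protocol durations in seconds; 30/30/10/10/5 are fixed by the
    # exercise definitions, 3 and 7 have no stated duration (10 reaches,
    # one chair rise), 8 is a short walk
    return {1: 30.0, 2: 30.0, 3: 20.0, 4: 10.0, 5: 10.0, 6: 5.0, 7: 3.0, 8: 20.0}


@dataclass
class SimulationConfig:
    """Cohort-level generator settings (units: s, Hz, m/s^2)."""

    seed: int = 0
    n_subjects: int = 6
    n_controls: int = 0
    trials_per_subject: int = 4
    trials_schedule: list[int] | None = None  # per-subject override
    sampling_rate_hz: float = 50.0
    tremor_freq_hz: float | None = None  # None: per-subject U(3.5, 7.5)
    tremor_amp_per_score: float = 0.25  # m/s^2 per score unit; 0 at score 0
    cycle_rate_base_hz: float = 2.0  # pronation-supination rate at score 0
    cycle_rate_slope: float = 0.3  # Hz lost per score unit
    cycle_amp_base: float = 1.5  # m/s^2 at score 0
    cycle_amp_slope: float = 0.25  # m/s^2 lost per score unit
    noise_sd: float = 0.05
    gravity_vector: tuple[float, float, float] = (0.0, 0.0, 9.81)
    exercise_durations_s: dict[int, float] = field(default_factory=_default_durations)
    rest_between_s: float = 10.0
    transition_range_s: tuple[float, float] = (1.0, 3.0)
    severity_probs: tuple[float, ...] = (0.25, 0.25, 0.2, 0.2, 0.1)
    week_jitter_p: float = 0.1  # per-item chance of a +-1 score shift per week

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.n_subjects < 0 or self.n_controls < 0:
            raise ValueError("subject counts must be non-negative")
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")
        if any(d <= 0 for d in self.exercise_durations_s.values()):
            raise ValueError("all exercise durations must be positive")
        if self.rest_between_s <= 0:
            raise ValueError("rest_between_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tremor_amp_per_score < 0:
            raise ValueError("tremor amplitude map must be non-negative")
        if self.cycle_rate_slope <= 0:
            raise ValueError("cycle rate map must be strictly decreasing in score")
        if self.severity_to_cycle_rate(4) <= 0:
            raise ValueError("cycle rate must stay positive at score 4")
        if self.severity_to_cycle_amp(4) < 0:
            raise ValueError("cycle amplitude must be non-negative on scores 0-4")
        probs = np.asarray(self.severity_probs, dtype=float)
        if probs.shape != (5,) or np.any(probs < 0) or probs.sum() <= 0:
            raise ValueError("severity_probs must be 5 non-negative weights over scores 0-4")

    # --- monotone severity maps ------------------------------------------
    def severity_to_tremor_amp(self, score: int) -> float:
        """Tremor oscillation amplitude (m/s^2); exactly 0 at score 0."""
        return self.tremor_amp_per_score * score

    def severity_to_cycle_rate(self, score: int) -> float:
        """Pronation-supination cycle frequency (Hz), strictly decreasing."""
        return self.cycle_rate_base_hz - self.cycle_rate_slope * score

    def severity_to_cycle_amp(self, score: int) -> float:
        """Pronation-supination acceleration amplitude (m/s^2), decreasing."""
        return self.cycle_amp_base - self.cycle_amp_slope * score


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    trial_id: str
    severities: dict[str, int]
    tremor_freq_hz: float
    tremor_intervals: list[tuple[float, float]]  # (start_s, end_s), rest tremor

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "severities": self.severities,
            "tremor_freq_hz": self.tremor_freq_hz,
            "tremor_intervals": [list(iv) for iv in self.tremor_intervals],
        }


def _validate_severities(severities: dict[str, int]) -> dict[str, int]:
    out = {}
    for item in SCORED_ITEMS:
        score = severities.get(item, 0)
        if not (isinstance(score, (int, np.integer)) and 0 <= score <= 4):
            raise ValueError(f"severity for item {item} must be an integer in 0-4")
        out[item] = int(score)
    return out


def _tremor_wave(n: int, rate: float, f0: float, amp: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated sinusoid with bounded frequency jitter.

    The instantaneous frequency performs a random walk clipped to
    f0 +- 0.25 Hz so the spectrum is band-limited but not a pure line.
    """
    if amp == 0.0:
        return np.zeros(n)
    jitter = np.clip(np.cumsum(rng.normal(0.0, 0.02, n)), -0.25, 0.25)
    phase = 2 * np.pi * np.cumsum(f0 + jitter) / rate
    am = 1.0 + 0.2 * np.sin(2 * np.pi * 0.3 * np.arange(n) / rate + rng.uniform(0, 2 * np.pi))
    return amp * am * np.sin(phase + rng.uniform(0, 2 * np.pi))


def _oscillation(n: int, rate: float, freq: float, amp: float,
                 rng: np.random.Generator, ramp_s: float = 0.5) -> np.ndarray:
    """Sinusoidal voluntary-movement template with smooth onset/offset."""
    if amp == 0.0 or n == 0:
        return np.zeros(n)
    t = np.arange(n) / rate
    env = np.ones(n)
    k = min(n // 2, int(ramp_s * rate))
    if k > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        env[:k] = ramp
        env[-k:] = ramp[::-1]
    return amp * env * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))


def _bump(n: int, amp: float) -> np.ndarray:
    """Single smooth low-frequency burst (postural transition / chair rise)."""
    if n == 0:
        return np.zeros(0)
    return amp * np.hanning(n)


def _movement_direction(g_hat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit vector tilted 30-55 degrees from gravity.

    Limb movement and tremor always retain a substantial component along
    gravity (the wrist rotates in a gravity field), which is what makes the
    oscillation visible in the magnitude norm.
    """
    theta = np.deg2rad(rng.uniform(30.0, 55.0))
    # arbitrary perpendicular basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, g_hat)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(g_hat, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(g_hat, p1)
    phi = rng.uniform(0, 2 * np.pi)
    perp = np.cos(phi) * p1 + np.sin(phi) * p2
    return np.cos(theta) * g_hat + np.sin(theta) * perp


def simulate_trial(config: SimulationConfig, subject_id: str,
                   severities: dict[str, int], *, group: str = "supervised",
                   week: int = 1, rng: np.random.Generator | None = None,
                   tremor_freq_hz: float | None = None
                   ) -> tuple[TrialRecord, GroundTruth]:
    """Generate one weekly session for one subject.

    The trial is, in protocol order, a transition, the exercise, and a rest
    interval for each of the 8 exercises (exercise 1, the rest-tremor task,
    shares label 1 with the resting intervals). Tremor oscillation is
    injected during label-1 samples (rest-tremor score) and the postural
    hold (postural-tremor score).
    """
    severities = _validate_severities(severities)
    if rng is None:
        # stable across processes (str hash randomization would break determinism)
        sid = zlib.crc32(subject_id.encode()) % 2**31
        rng = np.random.default_rng([config.seed, sid, week])
    rate = config.sampling_rate_hz
    f_tremor = tremor_freq_hz if tremor_freq_hz is not None else config.tremor_freq_hz
    if f_tremor is None:
        f_tremor = rng.uniform(3.5, 7.5)

    g_vec = np.asarray(config.gravity_vector, dtype=float)
    g_hat = g_vec / np.linalg.norm(g_vec)
    u = _movement_direction(g_hat, rng)

    amp_rest = config.severity_to_tremor_amp(severities["3.17"])
    amp_post = config.severity_to_tremor_amp(severities["3.15"])

    def exercise_wave(code: int, n: int) -> np.ndarray:
        s = severities
        if code == 1:  # rest-tremor task: no voluntary movement
            return np.zeros(n)
        if code == 2:  # postural hold: slow sway
            return _oscillation(n, rate, 0.3, 0.08, rng)
        if code == 3:  # hand-to-chest reaches
            return _oscillation(n, rate, 0.5, 0.8, rng)
        if code == 4:  # finger tapping (weak at the wrist)
            return _oscillation(n, rate, 3.0 - 0.3 * s["3.4"], 0.35 * (1 - 0.12 * s["3.4"]), rng)
        if code == 5:  # hand open-close
            return _oscillation(n, rate, 2.5 - 0.25 * s["3.5"], 0.5 * (1 - 0.12 * s["3.5"]), rng)
        if code == 6:  # pronation-supination: the bradykinesia channel
            return _oscillation(n, rate, config.severity_to_cycle_rate(s["3.6"]),
                                config.severity_to_cycle_amp(s["3.6"]), rng)
        if code == 7:  # sit-to-stand
            return _bump(n, 1.2)
        if code == 8:  # gait
            return _oscillation(n, rate, 1.9 - 0.12 * s["3.10"], 1.2 * (1 - 0.1 * s["3.10"]), rng)
        raise ValueError(code)

    pieces: list[tuple[int, np.ndarray]] = []  # (label, movement-along-u)
    for code in range(1, 9):
        n_tr = int(round(rng.uniform(*config.transition_range_s) * rate))
        pieces.append((0, _bump(n_tr, 0.6)))
        n_ex = int(round(config.exercise_durations_s[code] * rate))
        label = 1 if code == 1 else code
        pieces.append((label, exercise_wave(code, n_ex)))
        n_rest = int(round(config.rest_between_s * rate))
        pieces.append((1, np.zeros(n_rest)))

    labels = np.concatenate([np.full(len(x), lab, dtype=int) for lab, x in pieces])
    movement = np.concatenate([x for _, x in pieces])
    n_total = len(labels)

    # tremor injection over contiguous label runs
    tremor = np.zeros(n_total)
    tremor_intervals: list[tuple[float, float]] = []
    for seg in segments_from_labels(labels):
        if seg.label_code == 1 and amp_rest > 0:
            tremor[seg.start:seg.end] = _tremor_wave(seg.n_samples, rate, f_tremor,
                                                     amp_rest, rng)
            tremor_intervals.append((seg.start / rate, seg.end / rate))
        elif seg.label_code == 2 and amp_post > 0:
            tremor[seg.start:seg.end] = _tremor_wave(seg.n_samples, rate, f_tremor,
                                                     amp_post, rng)

    along_u = movement + tremor
    axes = g_vec[None, :] + along_u[:, None] * u[None, :]
    if config.noise_sd > 0:
        axes = axes + rng.normal(0.0, config.noise_sd, axes.shape)

    t = np.arange(n_total) / rate
    signal = TriaxialSignal(t=t, ax=axes[:, 0], ay=axes[:, 1], az=axes[:, 2],
                            sampling_rate_hz=rate)
    trial = TrialRecord(subject_id=subject_id, group=group, week=week,
                        signal=signal, segments=segments_from_labels(labels),
                        scores=dict(severities))
    truth = GroundTruth(trial_id=trial.trial_id, severities=dict(severities),
                        tremor_freq_hz=float(f_tremor),
                        tremor_intervals=tremor_intervals)
    return trial, truth


def _draw_severities(rng: np.random.Generator, probs: np.ndarray) -> dict[str, int]:
    p = probs / probs.sum()
    return {item: int(rng.choice(5, p=p)) for item in SCORED_ITEMS}


def _jitter_severities(severities: dict[str, int], rng: np.random.Generator,
                       p: float) -> dict[str, int]:
    out = {}
    for item, s in severities.items():
        if p > 0 and rng.random() < p:
            s = int(np.clip(s + rng.choice([-1, 1]), 0, 4))
        out[item] = s
    return out


def simulate_cohort(config: SimulationConfig, out_dir: str | Path | None = None
                    ) -> list[tuple[TrialRecord, GroundTruth]]:
    """Generate a cohort: PD subjects with drawn severities plus healthy
    controls at severity 0; severities persist across a subject's weekly
    trials up to the configured week-to-week jitter.

    If ``out_dir`` is given, trials are written in the session layout under
    ``out_dir/sessions/`` with a manifest and ``ground_truth.json``.
    """
    n_total = config.n_subjects + config.n_controls
    if n_total < 1:
        raise ValueError("cohort needs at least one subject")
    schedule = config.trials_schedule
    if schedule is not None and len(schedule) != n_total:
        raise ValueError("trials_schedule must list one trial count per subject")
    probs = np.asarray(config.severity_probs, dtype=float)

    results: list[tuple[TrialRecord, GroundTruth]] = []
    for idx in range(n_total):
        is_control = idx >= config.n_subjects
        subject_id = f"hc{idx - config.n_subjects:02d}" if is_control else f"pd{idx:02d}"
        group = "control" if is_control else "supervised"
        subj_rng = np.random.default_rng([config.seed, idx])
        base = ({item: 0 for item in SCORED_ITEMS} if is_control
                else _draw_severities(subj_rng, probs))
        f_tremor = (config.tremor_freq_hz if config.tremor_freq_hz is not None
                    else subj_rng.uniform(3.5, 7.5))
        n_trials = schedule[idx] if schedule is not None else config.trials_per_subject
        sev = dict(base)
        for week in range(1, n_trials + 1):
            if week > 1 and not is_control:
                sev = _jitter_severities(sev, subj_rng, config.week_jitter_p)
            trial_rng = np.random.default_rng([config.seed, idx, week])
            results.append(simulate_trial(config, subject_id, sev, group=group,
                                          week=week, rng=trial_rng,
                                          tremor_freq_hz=f_tremor))

    if out_dir is not None:
        out_dir = Path(out_dir)
        sessions = out_dir / "sessions"
        dirs = []
        for trial, _truth in results:
            write_trial(trial, sessions / trial.trial_id)
            dirs.append(trial.trial_id)
        write_cohort_manifest(sessions, dirs)
        truths = [truth.to_dict() for _, truth in results]
        (out_dir / "ground_truth.json").write_text(json.dumps(truths, indent=1) + "\n")
        (out_dir / "config.json").write_text(
            json.dumps(config_to_dict(config), indent=1, sort_keys=True) + "\n")
    return results


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["exercise_durations_s"] = {str(k): v for k, v in d["exercise_durations_s"].items()}
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "exercise_durations_s" in d:
        d["exercise_durations_s"] = {int(k): float(v)
                                     for k, v in d["exercise_durations_s"].items()}
    for tup_key in ("gravity_vector", "severity_probs", "transition_range_s"):
        if tup_key in d:
            d[tup_key] = tuple(d[tup_key])
    return SimulationConfig(**d)
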