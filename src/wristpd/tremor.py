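"""Continuous rest-tremor labeling.

Parkinsonian rest tremor at the wrist concentrates in the 3.5-7.5 Hz band.
Tremor presence over a rest interval is labeled by sliding a window over
the gravity-free movement norm, computing the tremor-band power of each
window, and thresholding. Supra-threshold windows are dilated back to
sample spans; gaps shorter than ``merge_gap_s`` are merged and spans
shorter than ``min_duration_s`` dropped, producing interval labels a
reviewer could correct by hand.

The threshold has no universal value (it depends on sensor noise and
tremor amplitude); ``calibrate_threshold`` recovers one from a cohort with
known tremor ground truth by maximizing window-level Youden's J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import BandDefinition, band_power_from_psd
from .preprocess import NormSignal
from scipy import signal as sps


@dataclass
class TremorLabelConfig:
    band: BandDefinition = field(default_factory=lambda: BandDefinition("tremor", 3.5, 7.5))
    window_samples: int = 128
    overlap_fraction: float = 0.5
    threshold: float = 0.01  # (m/s^2)^2 band power
    min_duration_s: float = 1.0
    merge_gap_s: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def step(self) -> int:
        return max(1, int(round(self.window_samples * (1 - self.overlap_fraction))))


@dataclass
class TremorIntervals:
    """Detected tremor spans plus the per-window power trace for audit."""

    intervals: list[tuple[float, float]]
    window_times: np.ndarray  # window-center times (s)
    window_powers: np.ndarray  # tremor-band power per window


def window_band_powers(norm: NormSignal, cfg: TremorLabelConfig
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window tremor-band power of a high-passed norm.

    Returns (window start indices, window-center times, band powers).
    """
    a = norm.a
    rate = norm.sampling_rate_hz
    w, step = cfg.window_samples, cfg.step
    if len(a) < w:
        return np.array([], dtype=int), np.array([]), np.array([])
    starts = np.arange(0, len(a) - w + 1, step)
    nyq = rate / 2
    powers = np.empty(len(starts))
    for i, s in enumerate(starts):
        f, psd = sps.periodogram(a[s:s + w], fs=rate, window="hann",
                                 scaling="density")
        powers[i] = band_power_from_psd(f, psd, cfg.band, nyq)
    centers = norm.t[0] + (starts + w / 2) / rate
    return starts, centers, powers


def label_tremor(norm: NormSignal, cfg: TremorLabelConfig) -> TremorIntervals:
    """Threshold the windowed tremor-band power into tremor intervals."""
    starts, centers, powers = window_band_powers(norm, cfg)
    if len(starts) == 0:
        warnings.warn("segment shorter than one analysis window; no intervals")
        return TremorIntervals([], centers, powers)
    rate = norm.sampling_rate_hz
    w = cfg.window_samples
    active = powers > cfg.threshold

    # dilate supra-threshold windows to sample spans
    mask = np.zeros(len(norm), dtype=bool)
    for s, on in zip(starts, active):
        if on:
            mask[s:s + w] = True

    spans = _mask_to_spans(mask)
    spans = _merge_gaps(spans, int(round(cfg.merge_gap_s * rate)))
    min_len = int(round(cfg.min_duration_s * rate))
    spans = [(s, e) for s, e in spans if e - s >= min_len]
    t0 = norm.t[0]
    intervals = [(t0 + s / rate, t0 + e / rate) for s, e in spans]
    return TremorIntervals(intervals, centers, powers)


def _mask_to_spans(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _merge_gaps(spans: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not spans:
        return []
    merged = [spans[0]]
    for s, e in spans[1:]:
        ps, pe = merged[-1]
        if s - pe <= max_gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def interval_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Intersection-over-union of two time intervals."""
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def calibrate_threshold(window_powers: np.ndarray, window_truth: np.ndarray
                        ) -> tuple[float, float]:
    """Threshold maximizing window-level Youden's J against ground truth.

    ``window_powers``: tremor-band power per analysis window (pooled over a
    cohort's rest segments); ``window_truth``: boolean, whether tremor was
    actually injected in that window. Returns (threshold, J at threshold).
    Sweeps the midpoints between consecutive distinct observed powers.
    """
    powers = np.asarray(window_powers, dtype=float)
    truth = np.asarray(window_truth, dtype=bool)
    if powers.shape != truth.shape or powers.ndim != 1:
        raise ValueError("window_powers and window_truth must be 1-D and aligned")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("calibration needs both tremor and non-tremor windows")
    uniq = np.unique(powers)
    if len(uniq) == 1:
        candidates = uniq
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2
    best_t, best_j = float(candidates[0]), -np.inf
    for thr in candidates:
        pred = powers > thr
        sens = np.count_nonzero(pred & truth) / n_pos
        spec = np.count_nonzero(~pred & ~truth) / n_neg
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, float(thr)
    return best_t, float(best_j)


def cohort_rest_window_powers(trials_with_truth, cfg: TremorLabelConfig,
                              filter_spec=None):
    """Pool rest-segment window powers and ground-truth flags over a cohort.

    A window counts as tremor-positive when more than half of it overlaps a
    ground-truth tremor interval.
    """
    from .preprocess import FilterSpec, movement_norm

    if filter_spec is None:
        filter_spec = FilterSpec()
    all_powers, all_truth = [], []
    for trial, truth in trials_with_truth:
        rate = trial.signal.sampling_rate_hz
        for seg in trial.segments:
            if seg.label_code != 1 or seg.n_samples < cfg.window_samples:
                continue
            norm = movement_norm(trial.signal.slice(seg.start, seg.end), filter_spec)
            starts, _centers, powers = window_band_powers(norm, cfg)
            seg_t0 = seg.start / rate
            for s, p in zip(starts, powers):
                w_lo = seg_t0 + s / rate
                w_hi = w_lo + cfg.window_samples / rate
                overlap = sum(max(0.0, min(w_hi, b) - max(w_lo, a))
                              for a, b in truth.tremor_intervals)
                all_powers.append(p)
                all_truth.append(overlap > 0.5 * (w_hi - w_lo))
    return np.asarray(all_powers), np.asarray(all_truth, dtype=bool)
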