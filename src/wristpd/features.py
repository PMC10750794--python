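"""Digital indicators: per-segment band-power features and windowed
activity-recognition features.

Two feature sets are computed:

(a) A 15-value per-segment set on the movement-magnitude norm of each whole
    exercise segment: 8 time-domain statistics (std, mean, median, 25th/75th
    percentile, skewness, max, min) and 7 band powers over symptom-specific
    frequency bands (freezing of gait 3-8 Hz, tremor 4-6 Hz, extended tremor
    3-8 Hz, bradykinesia/dyskinesia 0-3 Hz, gait 1-3 Hz, dyskinesia 1-4 Hz,
    full movement band 0-20 Hz). This set feeds the severity-correlation
    analysis.

(b) A windowed set on sliding 2.56 s / 128-sample windows with 50% overlap,
    computed per channel over the raw axes, the Euclidean norm and the jerk
    of each, used for exploratory embedding. The registry of feature
    families is configurable.

Band power is the integral of the one-sided Welch power spectral density
over [f_lo, f_hi), evaluated as the Riemann sum df * sum(PSD) over the
frequency bins in the half-open band so that disjoint bands are exactly
additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .io import TrialRecord
from .preprocess import FilterSpec, NormSignal, movement_norm


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"band {self.name}: need 0 <= f_lo < f_hi")


#: Symptom-band registry for the per-segment feature set.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("freeze", 3.0, 8.0),
    BandDefinition("tremor46", 4.0, 6.0),
    BandDefinition("tremor38", 3.0, 8.0),
    BandDefinition("bradydysk", 0.0, 3.0),
    BandDefinition("gait", 1.0, 3.0),
    BandDefinition("dysk14", 1.0, 4.0),
    BandDefinition("full", 0.0, 20.0),
)

TIME_FEATURE_NAMES = ("std", "mean", "median", "p25", "p75", "skewness", "max", "min")


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window parameters; defaults give 2.56 s at 50 Hz."""

    window_samples: int = 128
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_samples < 8:
            raise ValueError("window_samples must be >= 8")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def step(self) -> int:
        return max(1, int(round(self.window_samples * (1 - self.overlap_fraction))))


def n_windows(segment_length: int, cfg: WindowingConfig) -> int:
    """floor((L - W) / (W*(1-overlap))) + 1 for L >= W, else 0."""
    if segment_length < cfg.window_samples:
        return 0
    return (segment_length - cfg.window_samples) // cfg.step + 1


def welch_psd(a: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (Hann, density scaling, nperseg = min(256, L))."""
    nperseg = min(256, len(a))
    return sps.welch(a, fs=rate_hz, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, scaling="density")


def band_power_from_psd(f: np.ndarray, psd: np.ndarray, band: BandDefinition,
                        nyquist: float) -> float:
    if band.f_hi > nyquist and band.f_lo >= nyquist:
        raise ValueError(f"band {band.name} lies entirely above Nyquist {nyquist} Hz")
    hi = min(band.f_hi, nyquist)
    mask = (f >= band.f_lo) & (f < hi)
    if not mask.any():
        return 0.0
    df = f[1] - f[0]
    return float(np.sum(psd[mask]) * df)


def band_power(norm: NormSignal, band: BandDefinition) -> float:
    """Power of the magnitude signal inside one frequency band ((m/s^2)^2)."""
    nyq = norm.sampling_rate_hz / 2
    if band.f_lo >= nyq:
        raise ValueError(f"band {band.name} outside [0, Nyquist={nyq}]")
    f, psd = welch_psd(norm.a, norm.sampling_rate_hz)
    return band_power_from_psd(f, psd, band, nyq)


def segment_features(norm: NormSignal,
                     bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                     min_spectral_s: float = 2.0) -> dict[str, float]:
    """The 15-feature vector of one exercise segment's movement norm.

    Time statistics are always computed; band powers require at least
    ``min_spectral_s`` of signal and are reported as NaN on shorter
    segments. Skewness of an all-constant segment is undefined (NaN).
    """
    a = np.asarray(norm.a, dtype=float)
    if a.size == 0:
        raise ValueError("empty segment")
    feats: dict[str, float] = {
        "std": float(np.std(a, ddof=0)),
        "mean": float(np.mean(a)),
        "median": float(np.median(a)),
        "p25": float(np.percentile(a, 25)),
        "p75": float(np.percentile(a, 75)),
        "max": float(np.max(a)),
        "min": float(np.min(a)),
    }
    if np.ptp(a) == 0:
        feats["skewness"] = float("nan")
    else:
        feats["skewness"] = float(spstats.skew(a, bias=False))

    long_enough = a.size >= min_spectral_s * norm.sampling_rate_hz
    if long_enough:
        f, psd = welch_psd(a, norm.sampling_rate_hz)
        nyq = norm.sampling_rate_hz / 2
        for band in bands:
            feats[f"power_{band.name}"] = band_power_from_psd(f, psd, band, nyq)
    else:
        for band in bands:
            feats[f"power_{band.name}"] = float("nan")
    return {name: feats[name] for name in
            list(TIME_FEATURE_NAMES) + [f"power_{b.name}" for b in bands]}


def jerk(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Discrete jerk: forward first difference scaled by the sampling rate."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("jerk needs at least 2 samples")
    return np.diff(x) * rate_hz


# ---------------------------------------------------------------------------
# Windowed activity-recognition feature registry
# ---------------------------------------------------------------------------

def _zero_crossings(x: np.ndarray) -> float:
    centered = x - np.mean(x)
    return float(np.sum(np.signbit(centered[:-1]) != np.signbit(centered[1:])))


def _lag1_autocorr(x: np.ndarray) -> float:
    xc = x - np.mean(x)
    denom = float(np.dot(xc, xc))
    if denom == 0:
        return 0.0
    return float(np.dot(xc[:-1], xc[1:]) / denom)


def _hist_entropy(x: np.ndarray, bins: int = 16) -> float:
    counts, _ = np.histogram(x, bins=bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _spectral(x: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(128, len(x))
    return sps.welch(x, fs=rate_hz, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, scaling="density")


def _spectral_features(x: np.ndarray, rate_hz: float,
                       bands: Sequence[BandDefinition]) -> dict[str, float]:
    f, psd = _spectral(x, rate_hz)
    total = float(np.sum(psd))
    out: dict[str, float] = {}
    if total > 0:
        out["dom_freq"] = float(f[int(np.argmax(psd))])
        out["spec_centroid"] = float(np.sum(f * psd) / total)
        p = psd / total
        p = p[p > 0]
        out["spec_entropy"] = float(-np.sum(p * np.log2(p)))
    else:
        out["dom_freq"] = 0.0
        out["spec_centroid"] = 0.0
        out["spec_entropy"] = 0.0
    nyq = rate_hz / 2
    df = f[1] - f[0] if len(f) > 1 else 1.0
    for band in bands:
        hi = min(band.f_hi, nyq)
        mask = (f >= band.f_lo) & (f < hi)
        out[f"bandenergy_{band.name}"] = float(np.sum(psd[mask]) * df)
    return out


def _skew_safe(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0
    return float(spstats.skew(x, bias=False))


def _kurt_safe(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0
    return float(spstats.kurtosis(x, bias=False))


#: Per-channel time-domain feature families for the windowed set.
TIME_REGISTRY: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda x: float(np.mean(x)),
    "std": lambda x: float(np.std(x)),
    "median": lambda x: float(np.median(x)),
    "mad": lambda x: float(np.median(np.abs(x - np.median(x)))),
    "min": lambda x: float(np.min(x)),
    "max": lambda x: float(np.max(x)),
    "iqr": lambda x: float(np.percentile(x, 75) - np.percentile(x, 25)),
    "energy": lambda x: float(np.mean(x**2)),
    "entropy": _hist_entropy,
    "skewness": _skew_safe,
    "kurtosis": _kurt_safe,
    "autocorr1": _lag1_autocorr,
    "zerocross": _zero_crossings,
}

#: Exercise -> MDS-UPDRS item pairing used to tag windowed rows.
SEGMENT_SCORE_ITEM = {1: "3.17", 2: "3.15", 4: "3.4", 5: "3.5", 6: "3.6", 8: "3.10"}


def windowed_features(trial: TrialRecord,
                      cfg: WindowingConfig = WindowingConfig(),
                      time_registry: dict[str, Callable] | None = None,
                      bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                      filter_spec: FilterSpec = FilterSpec()) -> pd.DataFrame:
    """Sliding-window feature table over one trial.

    Channels: high-passed axes ax, ay, az; movement norm; and the jerk of
    each. Windows that straddle a segment boundary are dropped so every row
    belongs to exactly one labeled activity. Each row carries the segment's
    label code and, for scored exercises, the item id and the trial's score.
    """
    if time_registry is None:
        time_registry = TIME_REGISTRY
    if not time_registry:
        raise ValueError("feature registry must be non-empty")
    from .preprocess import highpass

    rate = trial.signal.sampling_rate_hz
    filtered = highpass(trial.signal, filter_spec)
    norm = movement_norm(trial.signal, filter_spec)
    channels = {
        "ax": filtered.ax, "ay": filtered.ay, "az": filtered.az, "norm": norm.a,
    }
    rows = []
    for seg in trial.segments:
        k = n_windows(seg.n_samples, cfg)
        for w in range(k):
            s = seg.start + w * cfg.step
            e = s + cfg.window_samples
            row: dict[str, object] = {
                "trial_id": trial.trial_id,
                "subject_id": trial.subject_id,
                "label_code": seg.label_code,
                "window_index": w,
            }
            item = SEGMENT_SCORE_ITEM.get(seg.label_code)
            row["score_item"] = item if item else ""
            row["score"] = trial.scores.get(item, np.nan) if item else np.nan
            sma = 0.0
            jerk_sma = 0.0
            for ch_name, ch in channels.items():
                x = ch[s:e]
                for feat_name, fn in time_registry.items():
                    row[f"{ch_name}_{feat_name}"] = fn(x)
                row.update({f"{ch_name}_{k2}": v for k2, v in
                            _spectral_features(x, rate, bands).items()})
                jx = jerk(x, rate)
                for feat_name, fn in time_registry.items():
                    row[f"{ch_name}_jerk_{feat_name}"] = fn(jx)
                if ch_name != "norm":
                    sma += np.mean(np.abs(x))
                    jerk_sma += np.mean(np.abs(jx))
            row["sma"] = float(sma)
            row["jerk_sma"] = float(jerk_sma)
            rows.append(row)
    if not rows:
        warnings.warn("no window fits inside any segment; returning empty table")
        return pd.DataFrame()
    return pd.DataFrame(rows)


def segment_feature_table(trials: Sequence[TrialRecord],
                          bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                          filter_spec: FilterSpec = FilterSpec()) -> pd.DataFrame:
    """Per-exercise 15-feature table across trials.

    For each trial and each exercise label present, features are computed on
    the movement norm of the whole segment. Label 1 covers both the
    rest-tremor exercise and the inter-exercise resting intervals; the
    longest label-1 run (the rest-tremor task plus its adjacent rest) is
    used as exercise 1's segment.
    """
    rows = []
    for trial in trials:
        by_label: dict[int, list] = {}
        for seg in trial.segments:
            by_label.setdefault(seg.label_code, []).append(seg)
        for label, segs in sorted(by_label.items()):
            if label == 0:
                continue
            seg = max(segs, key=lambda s: s.n_samples)
            # filter the segment in isolation: no transient bleed from
            # neighbouring exercises through the 0.5 Hz high-pass
            seg_norm = movement_norm(trial.signal.slice(seg.start, seg.end), filter_spec)
            feats = segment_features(seg_norm, bands)
            item = SEGMENT_SCORE_ITEM.get(label)
            rows.append({
                "trial_id": trial.trial_id,
                "subject_id": trial.subject_id,
                "group": trial.group,
                "label_code": label,
                "score_item": item if item else "",
                "score": trial.scores.get(item, np.nan) if item else np.nan,
                **feats,
            })
    return pd.DataFrame(rows)
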