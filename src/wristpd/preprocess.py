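"""Gravity removal and movement-magnitude extraction.

The raw wrist signal is dominated by the gravity component, a quasi-DC
offset on each axis that rotates slowly with wrist posture. A third-order
Butterworth high-pass at 0.5 Hz removes it while passing everything above
~1 Hz essentially unattenuated (voluntary movement lives below 10 Hz,
parkinsonian rest tremor in 3.5-7.5 Hz).

Orientation dependence is removed by the per-sample Euclidean norm

    a_i = sqrt(ax_i^2 + ay_i^2 + az_i^2).

``movement_norm`` composes the two: norm of the raw axes first (gravity
then appears as a near-constant offset plus the projected movement), then
the high-pass on the norm. Filtering the signed axes first and taking the
norm afterwards would rectify any band-limited oscillation (|A sin| has
its power at DC and twice the tremor frequency), destroying the band
semantics every downstream feature relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import TriaxialSignal


@dataclass(frozen=True)
class FilterSpec:
    """High-pass Butterworth specification."""

    order: int = 3
    cutoff_hz: float = 0.5
    zero_phase: bool = True

    def validate(self, sampling_rate_hz: float) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not (0 < self.cutoff_hz < sampling_rate_hz / 2):
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={sampling_rate_hz / 2} Hz)"
            )


@dataclass
class NormSignal:
    """Scalar movement-magnitude stream on the trial's time grid."""

    t: np.ndarray
    a: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if len(self.t) != len(self.a):
            raise ValueError("t and a must have equal length")

    def __len__(self) -> int:
        return len(self.a)

    def slice(self, start: int, end: int) -> "NormSignal":
        return NormSignal(self.t[start:end], self.a[start:end], self.sampling_rate_hz)


def _min_length(spec: FilterSpec) -> int:
    # reflective padding of 3x order on each side must fit
    return 3 * spec.order + 1


def _apply_highpass(x: np.ndarray, spec: FilterSpec, rate_hz: float) -> np.ndarray:
    spec.validate(rate_hz)
    if len(x) <= _min_length(spec):
        raise ValueError(
            f"signal of length {len(x)} too short to filter; need > {_min_length(spec)} samples"
        )
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, padtype="even", padlen=3 * spec.order)
    return sps.sosfilt(sos, x)


def highpass(signal: TriaxialSignal, spec: FilterSpec = FilterSpec()) -> TriaxialSignal:
    """High-pass each axis identically (zero-phase by default)."""
    rate = signal.sampling_rate_hz
    return TriaxialSignal(
        t=signal.t,
        ax=_apply_highpass(signal.ax, spec, rate),
        ay=_apply_highpass(signal.ay, spec, rate),
        az=_apply_highpass(signal.az, spec, rate),
        sampling_rate_hz=rate,
    )


def highpass_norm(norm: NormSignal, spec: FilterSpec = FilterSpec()) -> NormSignal:
    """High-pass a scalar magnitude stream."""
    return NormSignal(
        t=norm.t,
        a=_apply_highpass(norm.a, spec, norm.sampling_rate_hz),
        sampling_rate_hz=norm.sampling_rate_hz,
    )


def euclidean_norm(signal: TriaxialSignal) -> NormSignal:
    """Per-sample root-sum-of-squares of the three axes."""
    a = np.sqrt(signal.ax**2 + signal.ay**2 + signal.az**2)
    return NormSignal(t=signal.t, a=a, sampling_rate_hz=signal.sampling_rate_hz)


def movement_norm(signal: TriaxialSignal, spec: FilterSpec = FilterSpec()) -> NormSignal:
    """Gravity-free movement magnitude: norm of the raw axes, then high-pass."""
    return highpass_norm(euclidean_norm(signal), spec)
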