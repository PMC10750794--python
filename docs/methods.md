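# Methods

## Signal model and preprocessing

A wrist accelerometer measures specific force: gravity (magnitude
9.81 m/s², direction set by wrist posture) plus movement-induced
acceleration plus sensor noise. At the 50 Hz sampling rate used throughout,
voluntary movement lies below ~10 Hz and parkinsonian rest tremor in
3.5–7.5 Hz, so a third-order Butterworth high-pass at 0.5 Hz separates
gravity from movement with negligible passband loss (|H|² =
(f/f_c)⁶/(1+(f/f_c)⁶): −42 dB at 0.1 Hz, −0.00004 dB at 5 Hz). The filter
is applied zero-phase (forward–backward) by default so that burst onsets
used for interval labeling are not delayed; a causal mode is available via
`FilterSpec(zero_phase=False)`. Edge transients are suppressed by
even-reflection padding of 3× the filter order, and per-exercise analyses
filter each segment in isolation so one exercise's energy cannot leak into
a neighbouring rest interval through the filter's long (~2 s) settling
tail.

**Order of norm and filter.** The movement magnitude is computed as the
Euclidean norm of the *raw* axes first, then high-passed
(`movement_norm`). The reverse order — filtering the signed axes and then
taking the norm — rectifies any band-limited oscillation: for tremor
A·sin(2πft) along a fixed direction the filtered-axes norm is A·|sin|,
whose spectrum sits at DC and 2f, destroying the symptom-band semantics
(a 5 Hz tremor would appear at 10 Hz, outside every tremor band). With the
chosen order, |g·ĝ + v(t)| ≈ g + v(t)·ĝ for |v| ≪ g, so the movement
component survives at its true frequency (scaled by its projection on
gravity) and gravity itself is a quasi-DC offset the 0.5 Hz high-pass
removes. Both primitives (`highpass` on axes, `euclidean_norm`) remain
independently available.

## Feature sets

*Per-segment set (15 values)* on each whole exercise segment's movement
norm: std, mean, median, 25th/75th percentile, skewness, max, min, and
band powers for freeze-of-gait 3–8 Hz, tremor 4–6 Hz, extended tremor
3–8 Hz, bradykinesia/dyskinesia 0–3 Hz, gait 1–3 Hz, dyskinesia 1–4 Hz and
the full 0–20 Hz movement band. Skewness uses the bias-corrected
Fisher–Pearson form and is reported missing (NaN) on constant segments,
where it is undefined. Percentiles use linear interpolation between order
statistics. Segments shorter than 2 s yield time features only; band
features are NaN.

*Windowed set* over 2.56 s / 128-sample windows with 50% overlap
(`floor((L−W)/(W(1−overlap)))+1` windows per segment of length L ≥ W;
windows straddling a segment boundary are dropped so each row belongs to
one activity). Channels: the three high-passed axes, the movement norm, and
the jerk of each (forward first difference × sampling rate). Per channel:
mean, std, median, MAD, min, max, IQR, energy, histogram entropy, skewness,
kurtosis, lag-1 autocorrelation, zero crossings, dominant frequency,
spectral centroid, spectral entropy, and the symptom-band energies; plus
signal-magnitude area over the triaxial group and its jerk. The registry is
a plain name→callable mapping and can be replaced per call.

## Spectral estimation

Band power is the integral of the one-sided Welch PSD (Hann window,
`nperseg = min(256, L)`, 50% overlap, density scaling) over the half-open
interval [f_lo, f_hi), evaluated as the Riemann sum `df · Σ PSD`. The
half-open rectangle-sum convention makes disjoint bands *exactly* additive
(a trapezoid over masked bins double-counts boundary bins), and the
full-band integral of a zero-mean signal converges to its variance. Welch
averaging noise scales roughly as 1/√(K·n_bins) with K the number of
averaged segments — about 2–4% on a 30 s record — so exact-variance
(Parseval) checks are run on multi-minute records where the estimator noise
is well inside the asserted 2%. The independent oracle in the tests is
direct periodogram integration.

## Synthetic cohort generator

The generator emulates the weekly assessment protocol: for each exercise, a
1–3 s low-frequency postural transition (label 0), the exercise itself, and
a 10 s rest interval (label 1). Exercise durations default to 30 s (rest
tremor), 30 s (postural hold), 20 s (10 hand-to-chest reaches), 10 s
(finger tapping), 10 s (hand open-close), 5 s (pronation-supination), 3 s
(one chair rise), 20 s (short walk); the rest-tremor task and the rest
intervals share label 1 (both are relaxed sitting with supported hands), so
exercise 1 merges with its adjacent rest into one label-1 run and the
longest label-1 run serves as the rest-tremor segment.

Signal channels, all along a per-trial movement direction tilted 30–55°
from gravity (wrist movement always retains a gravity-aligned component,
which is what the magnitude norm picks up):

- **Rest tremor** (labels 1 and 2): amplitude-modulated sinusoid at a
  per-subject frequency drawn uniformly in 3.5–7.5 Hz, with a random-walk
  frequency jitter clipped to ±0.25 Hz and 20% sinusoidal amplitude
  modulation, so the spectrum is band-limited but not a pure line.
  Amplitude = 0.25 m/s² per score unit (exactly 0 at score 0); the rest
  segments use the rest-tremor item score (3.17), the postural hold the
  postural-tremor score (3.15).
- **Pronation-supination** (label 6): sinusoid at cycle rate
  2.0 − 0.3·score Hz and amplitude 1.5 − 0.25·score m/s² — both strictly
  decreasing in the bradykinesia score, placing the fundamental inside the
  1–4 Hz dyskinesia band at low scores and pushing it below/weakening it at
  high scores, which is what produces the negative band-power correlations.
- **Other exercises**: simple parametric oscillation or burst templates
  (reaches at 0.5 Hz, tapping at ~3 Hz with mild severity slowing, gait at
  ~1.9 Hz, a single smooth burst for the chair rise). Only the rest-tremor
  and pronation-supination channels need quantitative fidelity for the
  recovery analyses; the rest provide realistic context and label variety.
- **Noise**: white Gaussian, default σ = 0.05 m/s² per axis — the noise
  floor of consumer MEMS accelerometers.

Severities are drawn per subject (defaults weighted toward mild scores, as
in early-stage cohorts), persist across that subject's weeks up to a
configurable ±1 jitter (default probability 0.1 per item per week), and
controls are fixed at 0. All randomness flows from one integer seed through
`numpy.random.default_rng([seed, subject, week])`; identical seed + config
give byte-identical session files.

**What the generator does not emulate:** biomechanically realistic limb
dynamics, gyroscope channels, medication ON/OFF fluctuation, sensor
dropouts, or inter-rater scoring noise. Consequently the recovered
feature–score correlations (r ≈ 0.9–0.97 at the default noise level) are
upper bounds: passing tests show the pipeline recovers a known association
with the correct sign and strength ordering, not that real patients would
yield those values.

## Tremor labeling and calibration

"Tremor magnitude" is operationalized as the 3.5–7.5 Hz band power of the
high-passed movement norm over sliding 128-sample windows (50% overlap),
estimated per window by a Hann periodogram. Windows above threshold are
dilated to their sample spans; gaps ≤ 0.5 s are merged and spans < 1 s
dropped — interval-style labels a reviewer could correct. No universal
threshold exists (it depends on sensor noise and tremor amplitude), so the
threshold is calibrated against ground truth by sweeping midpoints of the
observed window powers and maximizing Youden's J (sensitivity +
specificity − 1); calibration replaces the manual specialist review used in
clinical practice. A window counts as truly tremulous when more than half
of it overlaps an injected-tremor interval.

## Correlation and embedding

Pearson r uses `scipy.stats.pearsonr` (two-sided p from the t distribution,
n−2 df) after pairwise deletion of missing values; zero-variance input
raises an explicit error rather than returning NaN. The matrix pairs each
scored exercise with its item (1↔3.17, 2↔3.15, 4↔3.4, 5↔3.5, 6↔3.6,
8↔3.10); hand-to-chest reaches have no standardized item and the
sit-to-stand task yields only ~2–3 s of signal, so both are excluded by
default. p-values are reported unadjusted for parity with clinical
reporting of this analysis; `bh_adjust=True` adds Benjamini–Hochberg.

t-SNE (scikit-learn) embeds the windowed features after per-column
standardization (band energies would otherwise dominate mixed-unit
features), with PCA initialization, perplexity 30 (clamped to (n−1)/3 in
the pipeline), auto learning rate, 1000 iterations, and a fixed seed —
reproducibility is preferred over any particular hyperparameter claim.
Healthy-control rows carry score 0 as the brushing variable.

## Problem sizes and numerical choices

The bundled drivers use a 102-trial / 13-subject cohort matching the target
study's group structure; recovery and calibration analyses in the tests and
the acceptance script use 40-trial and 24-trial cohorts respectively, sizes
at which the recovered statistics are stable across seeds. CSV output uses
17-significant-digit floats (and round-trip parsing on read) so that
write→read is exact and reruns are byte-identical. Gaps longer than 3
sample periods in real recordings are reported, never interpolated, because
silent infill biases band powers; irregular timestamps are normalized by
linear interpolation onto the uniform grid.

## Known limitations

- The voluntary-movement templates are sinusoids with smooth envelopes;
  they carry no harmonic structure, so spectral features on exercises 3–5,
  7, 8 are cleaner than real data would be.
- The linearization |g + v| ≈ g + v·ĝ means movement orthogonal to gravity
  is attenuated in the norm; the simulator guarantees a gravity-aligned
  component, real recordings do not always.
- Threshold calibration needs ground truth (or manual labels) and both
  classes present; it cannot be run on an unlabeled cohort.
- t-SNE determinism holds for a fixed seed, library version and BLAS; the
  embedding's geometry (not its exact coordinates) is the meaningful
  output.
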