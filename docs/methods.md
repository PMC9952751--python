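# Methods

This note documents the models, numerical choices and limitations behind
`ppgvitals`. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and windowing

The input is a single-channel PPG sampled at fs (125 Hz in the reference
protocol) with time-stamped reference vitals: respiration rate RR in
breaths/min and SpO₂ in percent, typically 1 Hz monitor numerics. Records
are windowed into 32 s segments with 50 % overlap — long enough to contain
several breaths at the low end of the RR range (5 bpm = one breath per
12 s), short enough to treat RR and SpO₂ as locally constant. Trailing
partial windows are dropped rather than zero-padded, because padding would
bias every spectral feature. Windows are half-open `[start, start + 32 s)`
with 0-based sample indexing.

Per-segment labels summarize the reference samples falling inside the
window; the rule is configurable (`mean` default, `median`, `midpoint`)
because monitor numerics jitter and the right summary is a judgment call.
Segments without in-window reference samples are flagged unlabeled and
excluded from model fitting.

An optional flat-line/clipping screen (`quality_screen`) exists but is off
by default: rejection thresholds are dataset-specific and silently dropping
data is worse than modeling it.

## Preprocessing

**Low-pass filter.** A 6th-order Butterworth low-pass with 25 Hz cutoff,
applied forward and backward (`filtfilt`). The two passes square the
magnitude response — attenuation at frequency f is
`2 · 10·log₁₀(1 + (f/f_c)^12)` dB — and cancel all phase, so fiducial
timing is untouched. Edge handling uses odd-reflection padding of
`max(3·(order+1), fs)` samples: about one second, enough for the edge
transient to decay completely, which makes the operation time-reversal
symmetric to machine precision (~1e-15). The shorter conventional padding
of `3·(order+1)` samples leaves ~1e-4 asymmetry and visible transients in
32 s windows.

**Variational mode decomposition.** VMD decomposes the (mean-removed,
mirror-extended) segment into K band-limited modes u_k with center
frequencies ω_k by ADMM: a spectral Wiener-filter update
`û_k = (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²)`, a power-weighted
mean-frequency update for ω_k, and dual ascent (step τ) on the
reconstruction constraint, iterated until the summed relative change drops
below `tol` or `max_iter` is reached (non-convergence returns the best
iterate with a flag). Defaults K = 5, α = 2000, τ = 0, tol = 1e-7,
max_iter = 500 follow the widely used moderate-bandwidth regime; all are
exposed in config. The residual is defined as input minus mode sum, so
reconstruction is exact by construction; the dual-ascent constraint is
exercised separately in tests with τ > 0.

**Artifact rule.** The lowest-center-frequency mode is removed only when
its relative energy exceeds 30 % *and* its center frequency is below
0.1 Hz. The conjunction is deliberately conservative: respiratory content
starts at RR/60 = 0.083 Hz for RR = 5 bpm, and destroying the respiratory
band would destroy the RR signal itself. Decomposition runs on the
mean-removed signal so a DC offset cannot masquerade as a dominant drift
mode. Decisions are logged per segment, and the rule is idempotent on the
synthetic corpus (removing the drift mode once leaves no second dominant
sub-0.1 Hz mode).

## Pulse delineation

The literature names the landmarks but no specific detector, so the scheme
here is the package's own, tuned for recall of systolic peaks (timing
ratios and amplitude statistics dominate the feature set):

* heart-rate prior: the periodogram peak in 0.7–3.5 Hz sets the minimum
  inter-peak distance to 40 % of the estimated beat period;
* systolic peaks: local maxima with prominence ≥ 30 % of the segment's
  5th–95th percentile amplitude span;
* pulse feet: the minimum between consecutive systolic peaks (the leading
  beat searches a window before the first peak; the trailing beat is kept
  open-ended);
* dicrotic notch / diastolic peak: sign changes of a Savitzky–Golay
  smoothed first derivative (window 11 samples, order 3) in the diastolic
  interval; when the hump is merged into the decay and no sign change
  exists, the first interior local maximum of the second derivative serves
  as notch and the following local minimum as diastolic shoulder;
* a–e waves: the first five alternating extrema of the smoothed second
  derivative after the foot.

Amplitudes are measured relative to the preceding foot value, since
filtering does not guarantee a zero baseline. Beats violating the ordering
invariants (foot < peak < next foot, positive systolic amplitude) are
discarded and counted; fewer than 3 valid beats marks the segment
unanalyzable, in which case beat-derived features are missing but spectral
and statistical features are still computed. Pulse widths at 25/50/75 % of
the systolic amplitude interpolate the threshold crossings linearly on each
side of the peak; a level never crossed (clipped or merged beat) yields a
missing width for that beat.

## Feature catalog (107 features)

The catalog is fixed, ordered, versioned, and contract-enforced at import
(exactly 107 unique names — any future change must preserve the count):

* **time (39)** — mean/SD/variance over beats of 13 pulse quantities:
  systolic, diastolic and notch amplitudes, t1 (foot → systolic peak), tpi
  (pulse interval), t1/tpi, rise and fall times, widths at 25/50/75 %,
  diastolic/systolic amplitude ratio, notch timing ratio;
* **derivative (22)** — mean/SD over beats of the a–e wave amplitudes, the
  b/a…e/a ratios, and two composite indices (b−c−d−e)/a and (b−c−d)/a;
* **frequency (17)** — global spectral maximum (frequency and magnitude),
  dominant frequency and magnitude in the cardiac band (0.7–3.5 Hz) and the
  respiratory band (0.05–0.6 Hz), the top-3 PSD peaks, relative band powers
  (respiratory, cardiac, harmonic 3.5–10 Hz), spectral centroid, spectral
  entropy;
* **statistical (29)** — mean, median, SD, variance, skewness, kurtosis,
  RMS, IQR, median absolute deviation, amplitude-histogram Shannon entropy
  and mean-crossing rate of the segment, Hjorth mobility and complexity,
  plus moment sets of the first (8) and second (8) differences.

Conventions, stated because they are frequently left implicit: skewness and
kurtosis are population moments with kurtosis non-excess (Gaussian = 3,
sine = 1.5); Shannon entropy uses a 16-bin histogram spanning the segment's
min–max with base-2 logs; spectra are Hann-windowed periodograms of the
mean-removed segment, zero-padded (nfft ≥ 2¹⁵) so band-dominant frequencies
are read on a fine grid (~0.004 Hz at 125 Hz) rather than the 1/32 Hz
native resolution — this matters for RR, where 1/32 Hz corresponds to
1.9 breaths/min.

Missing features (undetectable landmarks, unanalyzable segments) are
median-imputed *from training rows* inside each CV fold before model
fitting.

## Feature ranking

* **GP-ARD**: a Gaussian process with ARD squared-exponential kernel plus
  noise term, hyperparameters by L-BFGS-B on the log marginal likelihood;
  relevance of feature d is exp(−ℓ_d). The gradient over all length scales
  is assembled with matrix products in O(n²p), which keeps p ≈ 100
  tractable; log length scales are bounded so ignored features report tiny
  but strictly positive relevance (ℓ ≤ 500). Zero-variance columns leave
  the likelihood flat in their length scale, so they are excluded from the
  fit and pinned below the floor. Restarts are a failure-recovery path
  (non-finite likelihood), not a multi-start sweep, keeping the fit
  deterministic.
* **RReliefF** (regression ReliefF): every instance is used (no
  subsampling, for determinism), k = 10 nearest neighbors with rank-decayed
  influence exp(−(rank/σ)²), σ = 50, range-normalized differences, and the
  standard three-accumulator update
  `W_f = N_dYdF/N_dY − (N_dF − N_dYdF)/(m − N_dY)`.
* **LASSO path**: features are ranked by the largest penalty at which their
  coefficient is nonzero along a 100-point log-spaced path from λ_max
  (where all coefficients vanish) down to 10⁻³·λ_max; ties break by
  coefficient magnitude at the smallest penalty. Never-active and
  zero-variance columns rank last.
* **Laplacian score** (unsupervised): heat-kernel weighted symmetric 5-NN
  graph (kernel width = mean squared neighbor distance), locality score
  `L_f = f̃ᵀLf̃ / f̃ᵀDf̃`, importance −L_f.

Default subset sizes are 8 features for RR and 11 for SpO₂, exposed as
`--top-n`; a validation-fold sweep is the intended way to choose n for new
data.

## Regression protocol

Rows are shuffled once by seed and cut into 5 contiguous blocks; fold i
tests on block i, validates on block (i+1) mod 5 and trains on the
remaining 60 %. The five test sets partition the data. All fitted state —
imputation medians, standardization parameters, rankings, variant choice,
model parameters — derives from each fold's train (+validation for variant
choice) rows; `audit_no_leakage` re-runs the fold pipeline with test rows
overwritten by garbage and asserts bit-identical fitted state.

Folds are built at segment level by default, mirroring the reference
protocol. This lets overlapping windows of one recording straddle folds and
is therefore optimistic for subject generalization;
`make_grouped_cv_plan` provides the subject-disjoint alternative.

The model zoo ships 19 named presets across the five families (3 GPR, 4
SVR, 4 ensemble-tree, 4 decision-tree, 4 linear). The headline model is GPR
with the ARD kernel; its implementation is shared with the GP-ARD ranker
and is cross-checked in tests against scikit-learn's
`GaussianProcessRegressor` under a fixed kernel. RR and SpO₂ are always
separate models — they weight different features.

## Metrics

All error metrics use the population (divide-by-n) convention; sample
(ddof = 1) SD is available behind a flag. R = 1 − MSE(model)/MSE(baseline)
with the baseline predicting mean(truth) — a coefficient-of-determination
form, *not* Pearson r; both are reported because published "R-values" are
often ambiguous between the two. Limits of agreement are bias ± 1.96·SD of
the error (95 % under normality), with the (mean, difference) point cloud
exported for Bland–Altman plots.

## Synthetic data generator

Each segment is a train of two-Gaussian beats: beat k at time t_k (integer
crossings of a cardiac phase whose instantaneous rate is
hr·(1 + fm·sin(2πf_R t))), waveform
`A_k·[G(t; t_k+τ₁, σ_sys) + ρ·G(t; t_k+τ₂, σ_dia)]` with
`A_k = 1 + am·sin(2πf_R t_k)`, plus baseline wander `bw·sin(2πf_R t)`,
white noise at a configurable SNR, and Poisson-placed low-frequency
Gaussian bumps as motion artifacts. Defaults: am = 0.10, fm = 0.03,
bw = 0.15 (within the range reported for respiratory modulation of PPG),
SNR = 25 dB, 0.5 artifacts/min. Corpus draws are uniform: RR ∈ [5, 25]
breaths/min, SpO₂ ∈ [84, 100] %, HR ∈ [55, 95] bpm — the study-population
ranges for the first two; the HR range is a typical adult ICU spread.

Pulse-shape parameters are *fractions of the beat period* (σ_sys = 0.11,
σ_dia = 0.20, peak offset 0.30, diastolic offset 0.55) rather than absolute
seconds, so the morphology stays valid across the 40–180 bpm range used in
detector stress tests. The SpO₂ link is a declared surrogate:
ρ = 0.30 + 0.02·(100 − SpO₂) and σ_sys inflated by 1 + 0.01·(100 − SpO₂).
Single-channel PPG cannot encode true two-wavelength oximetry; the link
exists so the SpO₂ regression path is learnable and testable, not as a
physiological claim.

Ground-truth landmarks are located numerically on the clean waveform (the
foot is the waveform minimum between peaks, which for a smooth two-Gaussian
beat sits slightly before the template anchor — the truth t1/tpi is ≈ 0.35
at the default shape, not the 0.30 anchor offset), so detector accuracy is
scored against what the waveform actually does.

**What passing tests on this generator do and do not show.** They show the
machinery is correct: modulations are recovered, landmarks are found to
sample accuracy, selectors find the features that carry signal, the CV
protocol is leak-free, and metrics match their definitions. They do not
show clinical performance: real PPG has richer morphology (a genuine
e-wave, disease variants), non-stationary artifacts, sensor-dependent
waveform shapes, and reference vitals with their own error. The two-Gaussian
beat has only four second-derivative curvature extrema, so e-wave features
are missing on clean synthetic data and are exercised only through the
imputation path. Accordingly, synthetic MAEs (well under 1 breath/min /
1 %) are a correctness floor, not a performance claim.

## Problem sizes in the shipped runs

The test suite exercises the full protocol on a 1000-segment corpus (the
size at which the end-to-end recovery contract is asserted) and smaller
corpora (30–80 segments) for unit-level checks; `scripts/acceptance.py`
defaults to 500 segments, which reproduces the same qualitative results in
a few minutes on one CPU. All runs are deterministic given their seed.

## Known limitations

* The BIDMC comparison is informational only: the published corpus applies
  an unstated quality screen (1400 segments where raw windowing of 53 × 8
  min recordings yields 1537) and unstated fold seeds, so exact numbers are
  not reproducible and are never asserted.
* The WFDB reader supports text headers with format-16 signals (the BIDMC
  layout); other WFDB formats need conversion or CSV export.
* Fold construction at segment level is optimistic (see above).
* The feature catalog's itemization beyond the anchor features is a
  reconstruction; the 107-count contract, not the identity of every entry,
  is the stable interface.
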