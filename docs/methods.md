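# Methods

This note documents the models implemented in `emgcycle`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Signal model and preprocessing

Raw sEMG is sampled at 1000 Hz (Nyquist 500 Hz). Two causal Butterworth
cascades, applied as second-order sections, band-limit each channel:
a 10th-order low-pass with 400 Hz cutoff and a 10th-order high-pass with
20 Hz cutoff. The high-pass reaches −60 dB at 10 Hz exactly (a 2× frequency
ratio at order 10 gives 20·log10(2¹⁰) ≈ 60.2 dB); a 10th-order Butterworth
low-pass cannot reach −60 dB only 50 Hz past a 400 Hz cutoff — the
achieved attenuation at 450 Hz (≈ −11 dB) is logged rather than silently
redesigning the filter at a different order or cutoff. Filtering is
single-pass (causal); the group delay is identical for every channel and
every segment, so between-segment spectral comparisons — the only use made
of the segments — are unaffected.

## Variability-ratio segmentation

Pedalling is treated as cyclostationary: each revolution produces one
activity burst per muscle with a repeating within-cycle pattern, so
segments aligned to burst onsets are spectrally comparable. Onsets are
found from the backward difference ΔS(t) = S(t) − S(t−1) via the windowed
variability V(t) = Σ_{τ=t}^{t+N−1} |ΔS(τ)| (N = 256 samples ≈ one third of
a pedal cycle at 90 rpm) and the before/after ratio
V_com(t) = V(t−N) / V(t). At a burst onset the trailing window is quiet
and the leading window active, so V_com dips to a local minimum; at a
burst end it peaks.

Numerical choices:

- The literal signed window sum of ΔS telescopes to S(t+N−1) − S(t−1) and
  measures nothing about variability; the default therefore sums absolute
  differences (the window's total variation). The signed variant is kept
  behind `mode="signed"` for comparison.
- The denominator of V_com is guarded by an epsilon scaled to the largest
  window variability (1e−12·max V), keeping the ratio — and hence every
  detected onset — exactly invariant under amplitude scaling.
- Minima are accepted if their prominence exceeds 0.2 of the range of
  V_com **clipped at 2.0**. The ratio's neutral value is 1 and onset
  minima lie well below it, while burst-end maxima are unbounded whenever
  the trailing window is near-silent; without the clip those maxima would
  inflate the prominence reference arbitrarily. Minima closer than 0.7 of
  the expected cycle (from the cadence) keep only the deepest.
- In noise-free signals V_com is exactly flat between bursts; plateau
  minima resolve to the plateau's right edge, the last quiet sample before
  activity.
- Onsets whose 256-sample window would overrun the recording are dropped.

On jitter-free synthetic recordings with default noise, detection recovers
every pedal stroke with a median onset error of 10–27 ms (the residual is
dominated by the causal filter delay and the burst's ~25 ms amplitude
ramp); the acceptance suite requires count equality and median error
< 32 ms (N/8).

## The 36 variables

Each segment is Hamming-windowed (0.54 − 0.46·cos coefficients) and its
one-sided squared-magnitude DFT P(f) is normalised to the unit-area power
distribution D(f) (Riemann sum, bin width fs/N = 3.90625 Hz). Variables,
in canonical order: RMS, dRMS, IF; ModF, MnF, StD, Skew, Kurt; q10..q90;
p23_47..p234_258. Conventions:

- IF is the zero-crossing count divided by two, reported as a count per
  segment, exactly as defined; all downstream models z-score inputs, so
  affine units are irrelevant. Crossings are strict sign changes with
  exact zeros skipped.
- The DC bin participates in the normalisation of D(f) but is excluded
  from the mode search (the high-pass makes it ≈ 0; a spurious 0 Hz mode
  is ruled out regardless). Kurtosis is excess (−3). A degenerate
  distribution (all mass in one bin) reports SD = 0 and skew/kurtosis 0.
- Percentiles treat bin k's mass as uniform over the bin-centred interval
  [f_k − Δf/2, f_k + Δf/2] and interpolate linearly inside the crossing
  bin; results are clipped to [0, 500] Hz. Consequently a point-mass
  distribution reports percentiles within half a bin of the mass
  location, not exactly at the bin centre.
- The 19 relative band powers sum raw-spectrum bins [6+3k, 6+3k+6) —
  6-bin-wide (23.44 Hz) bands offset by 3 bins (11.72 Hz) — and divide by
  the total power over the non-DC bins, so a flat spectrum puts 6/128 in
  every band.
- An all-zero segment reports all 36 variables as 0 with a warning rather
  than propagating NaN.
- Each variable is smoothed along the segment axis with a centred
  11-point running median (≈ 7–10 s of riding); edge windows shrink to
  the available samples.

## Targets and alignment

Lactate (sampled every 60 s) and VO2 (every 10 s) are interpolated **to
the segment timestamps** with cubic Hermite splines using Catmull–Rom
tangents: interior tangent (v[i+1] − v[i−1]) / (t[i+1] − t[i−1]), one-sided
at the endpoints. This preserves the per-revolution sampling density the
models are built on. Queries outside the measured span are an error, and
segments outside it are dropped — physiology is never extrapolated.

## Models

**Ridge.** Inputs and output are z-scored with training-split statistics
only (validation folds are transformed, never refit — no leakage);
zero-variance columns are dropped with a warning. With centred data no
intercept is needed and the weights solve (XᵀX + λI)β = Xᵀy. λ is chosen
by computing, for every integer λ in 1..100 and every available dataset,
the mean 10-fold CV R², averaging curves across datasets, smoothing with a
centred moving average of width 9, and taking the argmax (ties to the
smaller λ). Fold assignment depends only on the dataset and seed, so
duplicating a dataset cannot move the optimum. The λ-selection folds and
the evaluation folds are drawn independently.

**Forest.** 100 regression trees, each grown on an n-out-of-n bootstrap
sample with 12 (= ⌊36/3⌋) candidate variables per split; trees are
scikit-learn `DecisionTreeRegressor`s, while bagging, OOB bookkeeping and
importance are implemented here with explicit bootstrap index sets. A
row's OOB prediction averages the trees whose bootstrap missed it (≈ 1/e
of trees; rows in every bootstrap are excluded with a warning). OOB R² is
averaged over 10 independently seeded forests. Permutation importance is
the mean rise in per-tree OOB MSE after shuffling one column within the
tree's OOB rows; `normalize=True` rescales to sum 1 so 1/36 is the
"all equally important" reference. Targets are left raw for the forest
(trees are invariant to monotone input transforms).

**Evaluation.** R² = 1 − SS_res/SS_tot (0 for the mean predictor, may be
negative; defined as 0 with a warning for a constant target). Spearman's
coefficient uses the classical closed form 1 − 6Σd²/(n(n²−1)) on tie-free
data — exact ±1 for monotone relationships — and Pearson-on-average-ranks
when ties are present (ties do occur after median filtering); constant
inputs return NaN. Weight/importance distributions are summarised by 0.2
quantile segments with a two-sided one-sample t-test of mean ≠ 0 at
p < 0.05; no multiple-testing correction is applied, and the flags should
be read accordingly. Linear and forest models are compared with a
two-sided paired t-test on per-dataset R².

## Synthetic-data generator

The generator emulates a three-phase constant-load test: 6 min at 60 % of
VO2max power, a severe phase at 92.5 %, 6 min at 60 %, at 90 rpm and
1000 Hz. Defaults (units in parentheses):

- Lactate: dL/dt = a·max(0, load − θ) − c·L with baseline 1.0 mmol/L,
  threshold θ = 0.75 (load fraction), a = 0.13 (mmol/L/s per unit excess
  load), clearance c = 0.002 /s, observation noise SD 0.25 mmol/L
  truncated at 0, sampled every 60 s. These rates give the characteristic
  shape: low in phase 1, rising to ~7 mmol/L by the end of the severe
  phase, washing out with a ~8 min time constant in recovery.
- VO2: first-order lag (τ = 30 s) toward 0.5 + 3.0·load L/min, noise SD
  0.06 L/min, sampled every 10 s.
- Both ODEs are linear with piecewise-constant input and are advanced with
  exact exponential updates on a 1 s grid — no integrator error beyond
  the grid's resolution of phase boundaries.
- Latent exertion = load + 0.5·max(0, L − baseline)/10 couples EMG
  amplitude to accumulated lactate (fatigued riders recruit more), which
  is what makes lactate predictable from EMG amplitude in synthetic runs.
- EMG: one burst per revolution per channel; muscle-specific within-cycle
  phase (extensors on the downstroke, flexors later); onset jitter ±5 ms
  uniform (≤ 10 ms by contract); burst length one third of the cycle
  under a Tukey(0.25) envelope (~25 ms rise, so the envelope start is a
  meaningful onset); burst content is unit-RMS coloured Gaussian noise
  mixed from a 20–250 Hz and a 250–400 Hz band, with the high-band power
  fraction ("tail mass", default 0.15 ± 0.03 per-burst jitter, optional
  drift with exertion) exposed so experiments can plant signal in the
  upper spectral percentiles; amplitude = 0.5 mV per unit exertion;
  baseline noise SD 0.02 mV; 0.5 s lead-in before the first stroke. A
  single seeded generator drives everything: identical inputs give
  bit-identical recordings.

**Recovery experiments** (`emgcycle.experiments`) plant a target
y = sigmoid(3·z(RMS)) + N(0, 0.05) on fully pipelined synthetic channels.
These runs use a burst spectrum with large per-burst tail-mass jitter
(0.3 ± 0.2): with a near-fixed spectral shape dRMS is an almost exact
multiple of RMS and no importance measure could attribute the planted
signal to one of the two — the added spectral diversity makes RMS
identifiable. Under these conditions the 10-seed forest OOB R² exceeds
0.98, RMS attains maximal permutation importance on every replicate
channel (~2× the dRMS importance), and the forest beats ridge on all
replicates (paired p ≪ 0.05), because the saturating sigmoid is exactly
the regime where a linear model must lose.

## What passing tests show — and what they do not

The generator reproduces the *structure* of the measurement problem
(cyclostationary bursts, sparse asynchronous targets, load-coupled
amplitude and spectra) but not the physiology of real sEMG: no motor-unit
recruitment model, no electrode displacement or movement artifacts, no
inter-subject variability in electrode placement or adiposity, no
biomechanical force model, and amplitude–lactate coupling is inserted by
construction rather than discovered. Synthetic results therefore validate
the *implementation* (the pipeline recovers what was planted, estimators
match their oracles) — they are not evidence about the strength of
EMG–metabolite relationships in humans. Problem sizes in the test suite
and acceptance script (30–1800 cycles per recording, 8 replicate
channels, ~1000 segments per model) were chosen as the smallest sizes at
which the statistical claims are stable.

## Known limitations

- Causal filtering shifts all onsets by the filter group delay; absolute
  onset times carry this common bias even though segment comparisons do
  not.
- The λ grid is integer-valued 1..100 by design; data preferring λ > 100
  will saturate at the grid edge.
- Permutation importance inherits the usual caveat with correlated
  inputs: importance of a variable is diluted by the presence of close
  proxies (this is exactly the RMS/dRMS effect handled in the recovery
  experiment design).
- The paired t-test treats per-channel R² values as independent
  observations; channels from one synthetic session share a protocol and
  metabolic trajectory, so the test is anti-conservative for
  cross-session claims.
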