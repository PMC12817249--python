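# Methods

This note records the modelling choices behind `stressci`: the
generative model of the synthetic cohorts, the baseline and index
definitions, the numerical conventions, and what the synthetic results
do and do not establish about real wearable data.

## Synthetic biomarker model

The generator produces the statistical structure the analysis stages
assume, not a physiological simulation.

**Cortisol.** A strictly positive single-peak day curve,
`C(t) = basal + A · exp(κ(cos(φ − s·sin φ) − 1))` with
`φ = 2π(t − acrophase)/24`. This is a von-Mises-style bump with a skew
term; the skew vanishes at the peak and at the trough 12 h later, so the
acrophase and bathyphase are exact, and the curve is 24-h periodic by
construction. Defaults: basal 100 nM, amplitude 60 nM (drawn per subject
with SDs 6 and 8), κ = 2, skew = 0.3. The normal-schedule acrophase is a
configuration parameter defaulting to 08:00, and an inverted sleep
schedule shifts it by exactly 12 h — schedule, not clock time, drives
the rhythm. A coffee habit multiplies the whole curve by 1.15; reported
elevated sweat-cortisol in habitual coffee drinkers motivates the
uplift, the size is a default, not a measured effect.

**Glucose.** Basal level (80 ± 5 µM between subjects) plus one pulse per
meal, kernel `k(x) = (x/τ)·e^(1−x/τ)` (unit peak τ = 0.75 h after the
meal, zero before it). Default meals at 08:00, 12:30 and 18:30,
amplitude 40 µM (30 µM in the depression cohort). Superposition is
linear, so far-apart meals produce equal-height peaks.

**ST and HR.** Stationary around basal values (34.5 °C, 72 bpm); an
exercise habit lowers resting HR by 8 bpm. No day structure — which is
exactly why these two biomarkers get constant baselines downstream.

**Acute-stress events.** Each series is multiplied by
`1 + intensity · gain_b · k(t − onset − lag_b)` with a unit-peak kernel:
smoothstep rise to a peak 5 min after the stressor ends, then
exponential decay (half-life 15 min). The kernel is identically zero
before `onset + lag`, so pre-event values are conserved bit-exactly.
Default lags put the glucose response 12 min behind cortisol, matching
the delayed glycaemic reaction seen in stress-test recordings. The
gamma/smoothstep shape is a design choice; only the qualitative
rise–peak–recover course (peak minutes after the stressor, recovery
within the hour) is constrained by observation.

**Pulse waveforms.** Per beat, three Gaussian bumps — percussion, tidal,
dicrotic — with relative amplitudes 1 / 0.5 / 0.25 at intra-beat offsets
0 / 0.22 / 0.45 of the period, repeated at 60/hr, plus white noise at a
configured SNR (`signal variance / noise variance`). Sampled at 1 kHz by
default. Percussion-peak times are stored as ground truth. The
amplitudes and offsets are qualitative-morphology defaults.

**Psychometric scores.** Affine maps of a latent stress level, clipped
to each scale's range: STAI-S `= clip(19 + 10·latent, 20, 80)`, so the
latent levels 1/2/3 used for the low/mid/high acute-stress cohorts land
at 29/39/49 — straddling the 34/44 cutpoints with 5-point margins.
SCL-90, SDS and SAS use slopes 60/12/12 from their minima (90/25/25).
These anchors are constructions: the clinical score–stress relation is
not linear and the real scale noise levels are unknown.

**Depression cohort.** 49 subjects (ND 14, DR 12, MD 13, SD 10 — 26
healthy-side, 23 patient-side), three repeats each at uniform random
times in 08:00–22:00 → 147 rows. Group latent levels 0–3 shift the
biomarkers (defaults: +35% cortisol, +15% glucose, +0.3 °C, +8 bpm per
level). The cortisol effect was sized so adjacent groups sit roughly
three between-subject SDs apart on the adjusted scale (gap ≈ 56 nM vs
spread ≈ 20 nM): the default cohort is *deliberately* separable, serving
as a positive control for the ML stage. The zero-effect variant (all
slopes 0) is the matching negative control: features carry no label
signal, so any above-chance held-out accuracy would indicate leakage.
Demographics are drawn independently of group.

What passing tests on these cohorts shows: the pipeline recovers
structure it is built for, at the stated noise levels, and does not leak
information across subjects. What they do not show: performance on real
sweat-sensor data, where sensor drift, sweat-rate variation, missing
samples, non-linear scale relations and weaker group effects all exist
and none are modelled.

## Baselines and temporal coupling

Day curves B(t) are fitted over the 08:00–22:00 window by bounded
nonlinear least squares (`scipy.optimize.curve_fit`, ≤ 5000 function
evaluations, bounds derived from the data range). Candidate families:
cosinor (mesor, amplitude, acrophase), two-harmonic cosinor, skewed
single peak, meal-pulse sum (fixed meal times, free amplitudes and rise
time), and constant. Initialization is deterministic — mesor = mean,
amplitude = half range, acrophase = time of the maximum — so a fit is a
pure function of the data; there are no random restarts. Model selection
minimizes mean squared leave-one-out prediction error and refits the
winner on all points. Multi-day series are characterized first with STL
(statsmodels, series linearly resampled to 24 samples per period) to
check how much variance the daily component carries.

ST and HR use constant baselines taken from the 08:00 measurement; they
show no day pattern to fit.

**Retro-adjustment is multiplicative**: `v ↦ v · B(benchmark)/B(t)`,
benchmark 08:00. Chosen over an additive shift because the indices are
built on relative deviations `(v − B(t))/B(t)`, which the multiplicative
map preserves exactly; it is the identity at the benchmark and
idempotent. A positivity floor of `1e−6 ×` the fitted data mean guards
the ratio; a baseline below it raises rather than silently producing
huge adjustments.

Pooled "pretraining" baselines for the cohort stages are fitted on a
synthetic 11-volunteer panel (15 samples/day each). Pooling across
subjects assumes a shared curve *shape*; per-subject fits are supported
where a subject's own day series exists.

## Indices and classification

SSCI1 and SSCI2 are implemented exactly as defined above. Impact weights
come from OLS with intercept (statsmodels); rank-deficient designs raise
a collinearity error rather than returning pseudo-inverse weights. Note
that when the per-biomarker deviations are strongly correlated — as in
an acute-stress cohort where all biomarkers track the same latent level
— the individual weights are poorly identified even though the fitted
index predicts well; the index, not the weight vector, is the output.

Classification applies the 34/44 STAI-S cutpoints to
`intercept + Σ ωᵢ devᵢ` (the predicted-score interpretation; the
intercept-free sum is exposed as the literal index value). Intervals are
left-closed: scores of exactly 34 and 44 go to the higher state. The
warning trigger uses a reference maximum from a prior calibration
session with fraction 0.8; an online running-maximum variant is provided
separately and flagged as a deployment convenience, not the published
protocol.

## Chronic stage

Features (9): adjusted cortisol and glucose, raw ST and HR, gender
(binary-encoded), age, height, weight, mean BP. Min-max normalization is
fitted on the training partition only. Labels: the three scales are each
min-max normalized and combined with equal thirds; thresholds 0.08 /
0.24 / 0.40 cut the composite into ND/DR/MD/SD (boundary value goes to
the higher class), placed between the composites the generator's latent
levels 0–3 produce (≈ 0 / 0.16 / 0.32 / 0.49). Equal weights and these
cutpoints are package defaults, not clinical values. MD+SD form the
binary patient class.

The split is by subject (10 held-out subjects → exactly 117/30 rows),
never by record, so no subject contributes to both partitions. The five
classifiers are scikit-learn models with fixed seeds: random forest
(300 trees), RBF-SVM (C=10, probability via ensemble-free calibration),
Gaussian naive Bayes, gradient-boosted trees, and a 16-unit
single-hidden-layer MLP — the smallest architecture sensible for nine
features. Binary ROC/PR metrics use the summed patient-class
probability. SSCI3 regression is ordinary least squares on the same
normalized features; stability comparisons report the relative standard
deviation (per cent, ddof=1) of the index across one subject's day,
computed with and without retro-adjustment.

## Numerical conventions and edge cases

- Clock times are decimal hours (8.25 = 08:15); ISO timestamps are
  converted on read.
- Noise is additive Gaussian truncated at a small positive floor, the
  simplest positivity-preserving choice; at the simulated noise scales
  truncation is a < 0.1% perturbation of the distribution.
- HR readout: zero-phase (forward–backward) third-order Butterworth,
  default band 0.5–5 Hz covering 30–200 bpm fundamentals; refractory
  0.3 s caps detectable HR at 200 bpm; prominence threshold 0.3 of the
  filtered range; equal-height plateaus resolve to the earliest sample;
  HR is 60 / median inter-beat interval (median, not mean, so isolated
  missed/extra peaks do not move the estimate); fewer than 3 beats →
  `too_short`, widely dispersed intervals → `low_snr`.
- LOOCV loss is mean squared error. Families that fail to fit are
  skipped during selection; if all fail, selection errors out.
- Missing biomarkers are never imputed: indices report missing and
  feature assembly raises, because silent imputation would corrupt
  classification.

## Problem sizes

Monte-Carlo suites use 100 replicate cohorts (500 for the
weight-coverage check, whose per-coefficient binomial error at 500
replicates is ≈ 1%); cohort analyses use the default 147-record design;
pulse traces are 30 s at 1 kHz. These sizes give the property checks
comfortable statistical margins while keeping a full run of the suite
and the acceptance script to a few seconds each.

## Known limitations

- No pharmacokinetic cortisol secretion model, no sweat-rate or sensor
  electrochemistry; the generator's circadian shapes are phenomenological.
- The pooled baseline assumes a shared day-curve shape across subjects;
  real inter-individual chronotype variation would degrade
  retro-adjustment and is not simulated beyond acrophase configuration.
- Scale-combination weights, four-group cutpoints and acute-stress
  effect sizes are package defaults chosen for a well-posed synthetic
  problem; none are clinically validated values.
- Heart-rate variability metrics and motion artifacts are out of scope.
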