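# stressci

Composite stress indices from wearable biomarker panels.

Wearable sweat-sensing platforms can track a four-biomarker stress panel —
sweat cortisol (nM), sweat glucose (µM), skin temperature (°C) and heart
rate (bpm) — continuously and non-invasively. Turning those raw panels
into an interpretable stress readout is a statistics problem: cortisol
follows a strong circadian rhythm and glucose follows meals, so the same
measured value means different things at 08:00 and at 20:00. `stressci`
implements the full analysis chain for that problem, runnable end to end
on seeded synthetic cohorts that emulate the relevant study designs
(circadian tracking, psychosocial stress tests, cold-pressor calibration,
a depression cohort), so every stage is testable without clinical data.

## The three indices

**SSCI1** — unweighted superposition of relative changes against a
per-test control value (pre-test or stable-period level):

```
SSCI1 = Σᵢ (biomarkerᵢ,measure − biomarkerᵢ,control) / biomarkerᵢ,control
```

Suitable for before/after comparisons within one stress session, and the
quantity streamed into the warning trigger (fires when SSCI1 reaches 80%
of a calibrated reference maximum).

**SSCI2** — weighted sum of *temporally coupled* relative deviations.
Each biomarker is compared against its fitted circadian day curve B(t)
over the 08:00–22:00 window, and the impact weights ω are estimated by
multiple linear regression of STAI-S anxiety scores on the deviations:

```
SSCI2 = Σᵢ ωᵢ · (biomarkerᵢ,measure&t − Bᵢ(t)) / Bᵢ(t)
```

Adding the regression intercept puts SSCI2 on the STAI-S scale, where
scores of 34 and 44 cut the acute-stress states Non-AS / Low AS / High AS.
Skin temperature is excluded in the cold-pressor configuration.

**SSCI3** — the chronic-stress index: the output of a model (five
compared classifiers for the depression groups ND/DR/MD/SD, linear
regression for the quantitative index) over a nine-feature vector:
cortisol and glucose retro-adjusted to the 08:00 benchmark via the
fitted baselines (`adjusted = v · B(8:00)/B(t)`), raw ST and HR, and
demographics (gender, age, height, weight, mean blood pressure).

Supporting stages: heart-rate readout from raw pulse waveforms
(zero-phase 0.5–5 Hz band-pass, prominence-thresholded peak detection,
median inter-beat interval), STL characterization of multi-day series,
bounded nonlinear least-squares day-curve fits (≤ 5000 function
evaluations) with leave-one-out cross-validated model selection, and a
subject-level 117:30 train/test split of the 147-record cohort.

## Worked example

The numbered drivers under `analysis/` run the whole chain on the
synthetic designs (seed 1) and write tables under `results/`:

```
$ python analysis/02_fit_baselines.py
[02] STL: seasonal component carries 99.2% of the cortisol variance over 3 days
[02] LOOCV picked harmonic2 for cortisol (loss 14.78) and meal_pulse for glucose (loss 43.73)
[02] within-day cortisol RSD: raw 20.2% -> adjusted 2.2%

$ python analysis/03_acute_stress_indices.py
[03] TSST: SSCI1 peaks at 0.99; warning (0.8 x reference max) fires at t=16.00 h (stressor onset 15.50 h)
[03] CPT weights (R^2=0.952): cortisol=47.2, glucose=18.7, hr=-17.3, intercept=18.4
[03] SSCI2 vs STAI-S correlation: 0.976; 3-state accuracy at the 34/44 cutpoints: 100.0% (n=60)

$ python analysis/04_chronic_stress_ml.py
[04] split: 117 train rows / 30 test rows (subject-level)
[04]                     RF: 4-class acc 1.000, ROC AUC 1.000, PR AUC 1.000
[04]                    SVM: 4-class acc 0.700, ROC AUC 0.974, PR AUC 0.988
[04]             NaiveBayes: 4-class acc 0.967, ROC AUC 0.995, PR AUC 0.998
[04]   GradientBoostedTrees: 4-class acc 0.933, ROC AUC 0.995, PR AUC 0.998
[04]                    ANN: 4-class acc 0.700, ROC AUC 0.979, PR AUC 0.991
[04] SSCI3 regression: test correlation 0.978 with the composite label
[04] day-tracked subject: SSCI3 RSD 4.2% with temporal processing vs 22.3% without
```

Reading the output: the STL decomposition confirms the simulated
cortisol series is dominated by its 24-h rhythm, which is why a raw
morning-vs-evening comparison is misleading; retro-adjustment to the
08:00 benchmark collapses the within-day spread by an order of
magnitude. In the acute-stress stage the regression-calibrated SSCI2
tracks the STAI-S anxiety score closely and classifies the three stress
states at the 34/44 cutpoints. In the chronic stage the random forest
resolves the four depression groups on held-out subjects, and the
temporally processed SSCI3 stays stable across a subject's day while
the unprocessed index swings with the circadian rhythm.

A `stressci` command-line tool exposes the same stages
(`stressci simulate|hr|fit-baseline|adjust|ssci1|fit-weights|ssci2|classify|warn|train-ssci3|evaluate|run`).

## Layout

```
src/stressci/     library: cohort, pulse, baseline, indices, chronic,
                  io, pipeline, cli
analysis/         numbered narrative drivers (simulate → fit → index → ML)
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance.py
docs/methods.md   modelling assumptions, defaults and limitations
```
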