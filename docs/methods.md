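# Methods

`nhpredict` implements a per-patient pipeline for predicting nocturnal
hypoglycemia (NH) — a glucose reading below 70 mg/dL (3.9 mmol/L) during
the night sleep period — in adults with type 1 diabetes on multiple daily
injections, from free-living continuous glucose monitoring (CGM) and a
wrist-worn activity tracker. Because no such cohort data is publicly
deposited, the package ships a synthetic free-living generator that plays
the role of the study cohort; everything downstream of the raw CSV
streams is agnostic to their origin.

## Data preparation

Raw streams are CGM glucose records at an irregular cadence of up to
15 min, manually logged rapid- and long-acting insulin doses (U), meal
carbohydrate estimates (g), fingerstick SMBG values, per-minute
steps/heart-rate/calories, and tracker-reported sleep periods. All
timestamps are timezone-naive local time and glucose is stored in mg/dL.

Preparation follows three stages:

1. **Resampling.** Glucose is snapped onto a uniform 5-min grid (288
   points per full day): each grid point takes the nearest raw record
   within ±2.5 min, ties resolved toward the earlier record; uncovered
   grid points are flagged missing.
2. **Imputation.** Interior missing runs are filled by linear
   interpolation between their bounding measured points whenever the
   anchor-to-anchor span is at most 120 min (≤ 23 consecutive missing
   points). Longer runs and runs at either edge of the trace stay
   missing. Each point carries a provenance flag (`measured` / `imputed`
   / `missing`). Note that with a 15-min sensor cadence, two of every
   three grid points are short-gap interpolations by construction.
3. **Activity alignment.** Per-minute activity rows aggregate into the
   5-min bins `[t, t+5)`: steps and calories are summed, heart rate is
   averaged; empty bins get zero steps/calories and missing heart rate.

## On-board physiological signals

Insulin on board (IOB) and carbohydrate on board (COB) use the standard
two-compartment impulse response with equal time constants: a dose or
meal of size `A` at elapsed time `t ≥ 0` contributes

    A · exp(−t/τ) · (1 + t/τ),

which equals `A` at the event, decays smoothly to zero, and superposes
linearly across events. Defaults: τ_ins = 75 min (rapid-acting insulin
absorption), τ_ch = 40 min (meal carbohydrate appearance). Long-acting
basal doses are recorded but excluded from IOB. Activity on board (AOB)
is a first-order leaky accumulator of gridded step counts with
τ_act = 120 min. The time constants are configurable; the specific
values are conventional artificial-pancreas-style choices, not fits.

## Night instances

One instance per calendar night. The night's sleep onset is the start of
the first tracker sleep period lasting ≥ 3 h that begins between 20:00
and 04:00; nights without such a period produce no instance (mirroring
tracker non-wear). Onset is snapped to the last grid point at or before
it. Two 72-point (6 h) windows are laid around the onset point: the
feature window ends at the onset point inclusive, the label window
starts at it. Nights with glucose coverage below 80% in either window
are discarded (logged, not raised). Imputed points count as readings for
both features and labels; `summarize_trace`-style exclusion of imputed
points is available via a flag.

The label is 1 if any non-missing reading in the label window is below
70 mg/dL. The 29 features comprise 25 CGM-signal descriptors plus one
IOB, one COB and two activity features, organised in 11 groups:

| group | features |
| --- | --- |
| endpoint | glucose at onset; mean of last 30 min |
| central | mean; median; last-hour mean |
| dispersion | SD; CV; IQR |
| extremes | min; max; range |
| rates | OLS slope (mg/dL/h); mean abs rate; max fall rate; max rise rate |
| ranges | % <70; % 70–180; % >180; % >250 |
| risk | LBGI; HBGI; AUC below 70 (mg/dL·min) |
| hypo history | episode count <70; minutes since last hypo (360 if none); any-hypo flag |
| iob | IOB at onset |
| cob | COB at onset |
| activity | AOB at onset; calories burned in window |

LBGI/HBGI use the Kovatchev symmetrised risk transform
`f(g) = 1.509·((ln g)^1.084 − 5.381)` with risk `10·f²`, averaging the
low-side (`f<0`) and high-side (`f>0`) contributions over all window
readings. Hypoglycemic episodes are maximal sub-70 runs; two runs merge
when the above-threshold stretch between them is shorter than 15 min.
Rates are computed between successive non-missing samples; time-in-range
boundaries follow consensus CGM conventions (70–180 closed, the other
cuts strict).

## Model evaluation

Models are personal: each patient's instances are evaluated in
isolation. A candidate model is a subset of the 11 feature groups fed to
either an RBF-kernel SVM (`C = 1`, kernel width `1/(q·Var)`, balanced
class weights) or a one-hidden-layer MLP (8 logistic units, ≤ 500
epochs, initialisation seeded per repetition). These hyperparameters are
deliberately plain defaults, exposed in `CVConfig`.

Scoring uses repeated stratified k-fold cross-validation (k = 5, default
100 repetitions). Per repetition `r` (fold seed = base seed + r), the
features are z-scored on each training part, the classifier predicts the
held-out fold, and the k folds' confusion counts are **pooled** into one
confusion matrix before computing sensitivity (SN), specificity (SP),
accuracy and

    Gmean = √(SN · SP).

Pooling keeps the metrics defined when a class has very few members
(a patient with 3 positive nights cannot yield per-fold SN). The
subset's score is the arithmetic mean over repetitions of per-repetition
Gmeans — not the Gmean of mean SN/SP, which by Jensen's inequality is
never smaller. Patients whose minority class is smaller than k get k
reduced to that count (minimum 2); repetitions with a degenerate
single-class training fold are skipped and logged.

The exhaustive search enumerates all 2^11 = 2048 group masks, skipping
the empty one (2047 evaluated), and ranks by mean Gmean with ties broken
toward fewer features, then lower mask value. Fold assignments depend
only on (labels, k, repetition seed) and are shared across masks.

## Synthetic cohort

The generator emulates the study's free-living conditions: 12 weeks per
patient (default), three jittered daily meals with carbohydrate-counted
boluses (1 U per 10 g, relative dosing error sd 0.35), one daily basal
dose, an evening activity bout (19:00 ± 45 min, 45 min, ~14 steps/min)
over ambient daytime steps, sleep onset 23:30 ± 30 min for ~8 h, CGM
emitted at a 15-min cadence with Poisson dropout gaps (0.6/day,
lognormal lengths, mean 45 min), and meal-time SMBG values.

Glucose follows a minimal linear-response model on a 5-min step around a
set point of 150 mg/dL: additive responses to the carbohydrate/insulin
appearance increments implied by the on-board curves (+3.5 mg/dL per g,
−35 mg/dL per U), a drain proportional to AOB, an extra nocturnal drift
while asleep (`basal_overdose`, with per-night lognormal variation,
σ = 0.25), AR(1) innovation noise (sd 0.3 mg/dL, coefficient 0.85), and a
homeostatic pull of 0.025 per step toward the set point. The pull term
keeps the 12-week trajectory stationary; without it the integrated AR
noise random-walks out of physiological range. Values are clamped to
[40, 400] mg/dL and sensor readings add small measurement noise.

The nocturnal drift is the NH-prevalence dial: the default 1.4 mg/dL per
step was calibrated once so that about one third of nights are labeled
positive (31.6% over ~1000 simulated nights; ~3% with the drift off),
matching the reference cohort's aggregate prevalence. Night-to-night
outcome variation mixes observable causes (dinner dosing error, evening
activity, pre-sleep glucose trajectory) with an unobservable per-night
drift factor, so classifiers can beat chance by a wide margin without
reaching perfection.

What the generator does **not** emulate: true meal-absorption physiology
(UVA/Padova-grade models), heart-rate-driven exercise response,
glucose-variability magnitudes of a hypoglycemia-prone cohort (its %CV
runs ~30% versus ~45% in such cohorts), sensor drift/recalibration, or
behavioural covariates (alcohol, menstrual cycle). Passing tests
therefore demonstrate that the pipeline machinery is correct and that
the learning protocol recovers planted structure — not that the specific
published per-patient sensitivities are reproducible, which would
require the original cohort.

## Problem sizes and numerical choices

The analysis drivers use a 10-patient × 84-day cohort with 3 CV
repetitions for the exhaustive SVM search and evaluate the MLP on the
full 29-feature vector (its exhaustive search costs two orders of
magnitude more); the test suite uses smaller cohorts, 2–5 repetitions
and a reduced end-to-end run. All randomness flows from explicit integer
seeds; identical configuration and seed reproduce every output file byte
for byte. Percentages render to two decimals; medians over even-sized
cohorts take the mean of the two central order statistics. Recomputing a
published median from printed (already-rounded) table values can land
exactly on a midpoint (e.g. 80.775) and differ from the printed median
by one final-digit unit; the package documents rather than resolves
this.
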