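# Methods

`cogstage` implements a forecasting pipeline for cognitive-stage
transitions in older adults monitored continuously at home. One row of raw
data is a subject-day of 13 activity measures derived from ambient sensors
(room dwell times, out-of-home episodes, five sleep measures, three walking
measures). The prediction target is the subject's cognitive stage —
cognitively healthy (CH), transitioning (TR), or mild cognitive impairment
(MCI) — at a future time point, given a block of past activity windows.

## Data model and labeling

Clinical stage is only observed at sparse assessment dates, and assessments
never carry TR: the decline from CH to MCI is gradual, so TR is *inferred*
— every day strictly between a subject's last CH assessment and the first
subsequent MCI assessment is labeled TR. All other days inherit the stage
of the most recent assessment (days before the first assessment inherit its
stage). Stages never improve within a subject (CH → TR → MCI → SI); input
violating that order is rejected. SI days are labeled but excluded from
model targets (the classifier is 3-class).

Assessment dates may lie outside the sensor-monitoring span. This is how
partially observed transitions are encoded: a subject still transitioning
when monitoring ends has their MCI conversion assessment dated after the
last activity day, and a subject already transitioning at baseline has the
anchoring CH assessment dated before day 0. The per-day labels inside the
span then follow from the single between-CH-and-MCI rule.

The calendar is abstract: integer day offsets, 7-day weeks, 30-day months,
90-day quarters, 360-day years. Nothing in the method needs real dates.

## Synthetic cohort generator

The generator supplies study conditions in place of restricted cohort data.
Each measure series is

    value(t) = baseline + stage drift(t) + weekly cycle(t) + AR(1) noise(t),

truncated at zero; count measures are rounded; total sleep is capped at 24
h. Defaults: AR(1) coefficient 0.5 with stationary marginal SD; latent
transition days drawn uniformly from the middle 60% of the span (avoiding
edge-degenerate label sequences); 3% of cells missing at random plus
contiguous 2–6-day blocks starting at rate 0.01/day; annual assessments.

The injected degeneration signal is deliberately expressed through two
channels:

* **level drift** — walking speed/count and out-of-home time decline,
  sleep disturbance (WASO, latency, night-time trips out of bed, daytime
  sleep in the living room) and bedroom/bathroom dwell rise. Drift is
  continuous across the TR → MCI transition: decline is gradual, so a
  late-TR window and an early-MCI window look locally alike.
* **variance inflation** — degenerating subjects become more erratic,
  most strongly in the sleep measures (day-to-day variability of sleep
  quantity and quality is an established decline marker), and more so in
  MCI (sleep variance ×3.0) than in TR (×2.5). Variability changes leave
  daily means untouched.

This construction gives each feature family in the modeling scenarios a
distinct role: raw window means see only the (mild) level drift;
distributional window statistics additionally see the variance signal;
full-series DTW distances additionally see each subject's global
trajectory. What passing benchmark tests show is therefore that the
pipeline recovers signal *placed where each feature family looks* — not
that real cohort data behaves this way. Other features of real data (wear
gaps correlated with health, seasonal effects, assessment-schedule
irregularity, informative missingness) are not emulated.

Default reference benchmark: 30 subjects (5 per trajectory), 360 days.

## Preprocessing

Cleanup removes exact-duplicate rows, subjects with no assessments,
subjects missing ≥ 80% of their measure cells overall, and rows with ≥ 90%
of measures blank ("almost all" made concrete as 0.90). Imputation fills a
missing cell from the subject's own observed block averages, escalating
week → month → quarter → year; the first two levels are the method's
explicit rule, the last two extend it using the same reference-average
granularities the method builds. If even the year block is empty the
subject-measure overall mean is used; a series with zero observations
anywhere is an error. Any number of missing days within a block is filled
(the rule is stated for "a few" days; no hard bound is imposed).
Imputation is idempotent and never alters an observed value.

## Features

Sliding windows of 10 days with stride 3: a 75% overlap of a 10-day window
is a 2.5-day skip, rounded to whole days. Six statistics per (window,
measure): median, mean, sample SD (n−1), coefficient of variation (SD/mean,
0 for constant windows, flagged 0 for zero-mean windows), adjusted
Fisher–Pearson skewness and bias-adjusted excess kurtosis (0 for constant
or too-short windows).

DTW uses the classic symmetric recurrence D(i,j) = |a_i−b_j| +
min(D(i−1,j), D(i,j−1), D(i−1,j−1)) with no window constraint and no path
normalization — the reference formulation, verifiable against exhaustive
path enumeration. Distances are computed between *full-length* daily
series, subject-to-subject, per measure; each subject's feature row repeats
its distance block (and demographics: age, gender coded male = 0 / female =
1, education years) across all windows. The reference cohort for distances
is the training cohort, fixed once, so feature dimensionality cannot drift
and evaluation subjects never enter the reference list.

A window's label is the stage of its last day (the window's most recent
information; the choice is a design decision, documented here). Scenario
feature sets: (1) per-window raw values — realized as the within-window
mean, the least-informative aggregation consistent with shared window
indexing — plus demographics; (2) window statistics + demographics; (3)
window statistics + DTW distances + demographics. All columns are z-scored
with training-split statistics: seconds-scale and cm/s-scale features
differ by orders of magnitude and the optimizer needs comparable scales.

## Sequence classifier

Samples are 10 consecutive windows with the label of the window immediately
after as target, cut every 2 windows (8-step overlap). Within every
subject, samples are split chronologically 75/15/10 into
train/validation/test; the earliest go to training, respecting the
forecasting framing. The literal ceiling rule is capped so every subject
with ≥ 3 samples reaches all three sets (train = min(⌈0.75n⌉, n−2),
validation = min(⌈0.15n⌉, n−train−1), rest test). Validation/test samples
whose input block reaches back to any window at or before the subject's
last training target are discarded — overlapping samples share 8 of 10
windows, and this removes the train-to-evaluation leakage path. A
permuted-label control (shuffled training targets must drop test accuracy
to chance) guards the protocol.

The classifier is a stacked three-layer LSTM (100/64/16 units) with
dropout 0.5 between recurrent layers and a 3-node softmax head on the final
timestep, trained with categorical cross-entropy and Adam at learning rate
1e-4 for 150 epochs by default. It is implemented directly in NumPy:
forward pass, backpropagation through time, and the Adam update, with
Glorot-uniform initialization, forget-gate bias 1, global gradient-norm
clipping at 5, and mini-batches of 16 (batch size is left open by the reference
configuration; 16 gives the low learning rate enough updates).
Float32 is the default precision; the gradient implementation is verified
against central finite differences in float64. Training is exactly
reproducible under a seed. Ties in the softmax argmax break toward the
more severe stage (MCI > TR > CH): in a screening context the costly error
is missing decline.

The benchmark uses a scaled-down 30-epoch profile; the problem sizes used
throughout (30 subjects, 360 days, 5 replicate seeds, 30 epochs) are the
package's desk-scale defaults and are recorded in every run manifest.

## Evaluation

Four accuracies, all percentages over subsets of true labels: overall; DIA
(true TR∪MCI); TIA (true TR); MIA (true MCI). A metric with an empty
denominator is undefined — reported as missing, never as 0 or 100 — and
undefined values are skipped when averaging replicates. DIA decomposes
exactly as the count-weighted mean of TIA and MIA.

Baselines (RBF-kernel SVM and random forest, default configurations)
receive each 10-step sample flattened to one vector — the same information
as the sequence model, making the comparison fair — on identical splits.
Paired comparisons use the two-sided Wilcoxon signed-rank test with the
exact small-sample null distribution, zeros dropped; the pairing unit is
the model configuration (paired across scenarios per metric). The pairing
is recorded in output metadata because the alternative reading (pairing
across runs) is also computable.

## Attribution

Shapley values are estimated by permutation sampling: a player is a
feature *column* (replaced across all 10 timesteps at once, so rankings
name features the way practitioners read them, not feature × timestep
cells); a coalition's value is the model's mean output over a fixed
background sample set with absent columns taken from the background. All
prefix coalitions of a permutation are evaluated in one batched model
call, and the telescoping sum makes the efficiency axiom (base value +
attributions = prediction) hold exactly for every estimate. An exact
full-enumeration oracle (≤ 10 players) verifies the sampler. The benchmark
explains the scenario-2 model (81 players; distance columns are
cohort-indexed and not meaningfully rankable as named features) with a
16-sample background, 6 explained samples and 8 permutations — sizes
recorded in the output.

## Numerical and degenerate-input conventions

Constant windows: SD, variation coefficient, skewness, kurtosis all 0.
Zero-mean windows: variation coefficient 0 with a logged warning. Empty
series: DTW errors. A subject with fewer windows than timesteps + 1 yields
zero samples with a warning. All-zero paired differences: Wilcoxon p = 1
with a warning. Replicate failures are logged and excluded rather than
fatal. Random draws all flow from `numpy.random.default_rng` seeded per
stage; derived seeds stay below 2^31.

## Known limitations

* The generator's day-level emulation cannot establish that the scenario
  ordering observed on it transfers to real sensor cohorts; the benchmark
  is a recovery test of planted signal, qualitative by design.
* With stride-2 overlapping samples, the leakage-discard rule consumes
  roughly half of each subject's validation/test samples; spans under
  about 200 days leave no evaluation samples per subject.
* The sampling Shapley explainer is priced for dozens of players;
  scenario-3 feature spaces (hundreds of cohort-indexed distance columns)
  are out of its intended range.
* Subject synthesis fits level + trend + AR(1) per stage segment; it
  preserves first/second-order temporal structure but not higher-order or
  cross-measure dependence.
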