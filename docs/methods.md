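# Methods

This note documents the models, conventions and numerical choices behind
`exhypo`, and what the synthetic-cohort tests do and do not demonstrate
about real data.

## Outcome and predictor definitions

**Outcome.** A bout is labelled hypoglycaemic if *any* CGM reading in the
half-open window `[start, start + duration)` is strictly below 3.9 mmol/l
(level-1 hypoglycaemia, 70 mg/dl). A single low reading suffices — in
free-living use people act on one low value, so sustained-episode
definitions (≥15 min) are deliberately not used. A reading exactly at the
bout start counts both as the starting glucose and as "during the bout";
a reading exactly at the end belongs to the next interval.

**Starting glucose** is the latest reading at or before the bout start, no
staler than 10 minutes (two cadence slots). An unbounded look-back would
silently use hours-old data after sensor dropouts, so staleness makes the
value *absent* instead; absent values flow to imputation.

**Rate of change** compares the starting reading with the reading nearest
to 15 minutes earlier (±5 min tolerance), divided by the *actual* elapsed
minutes between the two readings rather than the nominal lag — with
irregular cadence the nominal denominator biases the slope. Cut-offs:
falling < −0.05, rising > +0.05 mmol l⁻¹ min⁻¹, stable in between,
inclusive at both ends of the stable band.

**Insulin on board** decays linearly over a 4-h duration of insulin
action: a bolus of `u` units taken `dt` minutes ago contributes
`u·(1 − dt/240)` for `0 ≤ dt < 240`. Only logged boluses enter; basal
rates, suspensions and automated micro-boluses are not modelled.
Time-since-bolus categories use exact minutes (<90 / 90–210 / >210), with
the middle band closed on both sides since the verbal ranges
"<1.5 h / 1.5–3.5 h / >3.5 h" leave boundary membership open. Rounding the
elapsed time to the nearest hour before categorising would double-quantise
and was avoided.

**Data sufficiency** of a window is the reading count divided by the slot
count `window_minutes / 5`, capped at 1 for over-sampling devices; it
depends only on timestamps. Inclusion requires ≥60% during the bout and
≥40% in the prior hour. A bout whose prior-hour window extends before the
participant's record start fails the prior-hour criterion by construction.

**Overlap handling.** Exact duplicate bout records collapse to one kept
record. For a *partially* overlapping pair there is no principled
survivor, so both members are dropped — conservative, symmetric and
order-independent.

**Category mappings.** Borg 6–20 maps to light (<12), moderate (12–14),
vigorous (>14); out-of-range values become missing. Time-of-day bins are
half-open at the left edge (morning [05:00, 12:00), afternoon
[12:00, 17:00), evening wrapping midnight), so 12:00 — which touches two
verbal ranges — lands in the afternoon. Free-text exercise labels map to
aerobic/anaerobic/mixed through a case-folded lookup table; unmapped
labels become missing.

## Imputation

Missing cells are filled by k-nearest-neighbour imputation (k = 5).
Continuous features are standardised to the reference mean/variance;
distances are Euclidean over the mutually observed continuous features,
normalised by the number of features used. Continuous cells take the mean
of the k nearest donors with the feature observed; categorical cells take
the donors' majority vote, ties resolved by the overall most frequent
class. The outcome label is never a distance feature and never imputed.
The imputer has an explicit fit/transform split and is fitted on the
training folds of each CV split only, then applied to the validation fold
— without this discipline the validation fold's distribution leaks into
the fill-in values and the CV estimate is optimistic.

## Cross-validation and model

Folds group *participants*, not bouts, preserving within-person
correlation and preventing leakage (`assert_no_leakage` verifies the
property on every trained ensemble). Stratification uses a greedy
heuristic: participants in decreasing order of (hypo-bout count, total
bouts) are assigned to the fold where the marginal change in the fold's
absolute positive-count imbalance (plus a small size-parity term) is most
favourable. The balance achieved is asserted in tests (±3 pp of the
global prevalence), not assumed.

The classifier is XGBoost (`binary:logistic`, `hist`, single-thread for
determinism), defaults: 200 trees, depth 3, learning rate 0.08, subsample
0.9, column subsample 0.9, min child weight 5, L2 λ = 1. The
hyperparameter search is a seeded random search with a fixed budget
(default 25) over a documented grid; candidate 0 is always the default
configuration, so the selected configuration can never score below it on
the searched set.

**Class weighting.** The positive class is *not* up-weighted by default
(`scale_pos_weight = 1`, configurable). With ~9% positives a
negatives/positives weight would inflate predicted probabilities roughly
ten-fold, destroying the probability semantics of the traffic-light
categories while leaving ranking (ROC AUC) essentially unchanged. Because
the headline artifact is a calibrated risk grid, calibration wins.

**Thresholding.** The decision threshold maximises Youden's J
(sensitivity + specificity − 1) on out-of-fold predictions, computed per
fold and averaged; sensitivity/specificity are reported at that threshold
(`score ≥ threshold` ⇒ positive). The same threshold is carried, not
refitted, to external cohorts.

**Uncertainty.** Per-fold ROC AUCs are summarised as mean ± 1.96·sd/√k
(normal approximation, k = 10). Ensemble predictions for new rows are the
mean over the k fold models with the same normal-approximation CI.

**Forward selection** greedily adds the candidate maximising mean CV ROC
AUC, ties broken by candidate order, and reports the full trajectory
including zero/negative deltas (a `max_steps` parameter truncates it when
only the head of the ranking is needed). All dummy levels of categorical
candidates are kept as separate columns — tree models are indifferent to
the redundancy and the trajectory stays interpretable per level.

## Risk heatmap

The simplified model uses exactly starting glucose, planned duration and
the binary falling-trend indicator. The grid spans 4.0–14.0 mmol/l in 0.5
steps and 10–60 min in 5-min steps (configurable); duration is capped at
60 min, where predictive performance degrades. Categories partition
[0, 1]: very low [0, 1%), low [1%, 5%), moderate [5%, 20%), high
[20%, 100%] — left-closed bins, top bin closed, since "1–5%"-style ranges
leave boundary membership open. A monotone audit lists adjacent cells
where risk increases with glucose or decreases with duration by more than
0.01; an optional training mode enforces monotone constraints in the
booster (off by default — constraints are a presentation choice, not part
of the fitted model proper).

## Synthetic cohorts

The generator emulates a month-long free-living study: ~5-min CGM, three
jittered meal boluses per day plus corrections, and 10–120 min diary
bouts. Per participant, glucose is a mean-reverting AR(1) process around
a baseline drawn uniformly from 7.5–11.0 mmol/l, with φ = 0.98 per 5-min
step and innovation SD 0.45 mmol/l (stationary SD ≈ 2.3 mmol/l), clipped
to the conventional CGM reporting range 2.2–22.2 mmol/l. During a bout
the process acquires a downward drift

    drop/10 min = (0.35 + 2.0 · IOB/kg at start) · intensity factor,

with intensity factors 0.5/1.0/1.5 for light/moderate/vigorous (fixed,
arbitrary), plus a carry-over of 0.6 × the pre-bout 15-min trend.
Readings are deleted in geometric runs (mean 30 min) totalling 8% to
exercise the sufficiency filters; one engineered violation per exclusion
reason is appended by default so QC bookkeeping is testable exactly.
These defaults put the marginal bout-level hypoglycaemia rate in the
7–12% band typical of free-living cohorts, falling with starting glucose
and rising with duration.

Because the drift and the pre-bout latent state of every bout are
recorded, `true_risk` recomputes each bout's exact conditional
hypoglycaemia probability by Monte Carlo over the bout's own
missing-reading pattern. Conditional on that state, the generated label
is a Bernoulli draw with this probability, giving calibration tests a
perfectly calibrated oracle score.

**What the generator does not emulate:** physiological insulin–glucose
dynamics (no compartmental model), meal carbohydrates and their timing
relative to boluses, sensor noise artefacts (compression lows,
calibration steps), behavioural feedback (people eating carbs when low),
or realistic bout-timing distributions. Consequently the synthetic signal
is cleaner than reality: cross-validated ROC AUC on synthetic cohorts
(~0.95) exceeds what is attainable on real free-living data, and passing
tests demonstrate the *machinery* — leakage-free CV, calibration
recovery, monotone structure, determinism — not field performance.

## Problem sizes and determinism

Statistical tests run on a ~5,500-bout cohort (300 participants × 28
days), the null-distribution check on ~2,000 bouts with 20 label
permutations, and structural tests on smaller cohorts; the acceptance
script uses the same sizes. All randomness flows from explicit seeds
through `numpy.random.default_rng`; XGBoost runs single-threaded `hist`,
so two runs with the same seed produce byte-identical cohort CSVs and
metrics JSON.

## Known limitations

- The 4-h linear IOB model ignores insulin type and individual kinetics.
- Trend classes come from the stated rate-of-change cut-offs only;
  device-specific trend-arrow equivalence tables are out of scope.
- The volitional-exercise flag must be supplied upstream; distinguishing
  exercise from activities of daily living is not automatable here.
- Saved model bundles do not carry the fold imputers; loaded bundles rely
  on XGBoost's native missing-value routing for incomplete rows.
- The heatmap's fold-ensemble mean is one of several defensible choices
  for scoring grid cells (vs a single refit model); it matches how
  external cohorts are scored.
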