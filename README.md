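# exhypo

Predicting hypoglycaemia at the start of exercise in type 1 diabetes.

Fear of exercise-induced hypoglycaemia is a major barrier to physical
activity for people with type 1 diabetes. `exhypo` implements, end to end,
a pipeline that turns free-living continuous glucose monitor (CGM) traces,
bolus-insulin logs and exercise diaries into a per-bout risk model and a
four-colour traffic-light heatmap a person can read in seconds before
starting to exercise.

The pipeline:

1. **Bout quality control** — exercise bouts are excluded when their
   timestamp is unparseable, they are duplicated or overlapping, their
   duration falls outside 10–120 min, CGM data sufficiency is <60% during
   the bout or <40% in the prior hour, or the activity was not volitional
   exercise.
2. **Outcome** — level-1 hypoglycaemia: any CGM reading <3.9 mmol/l
   (70 mg/dl) during the bout.
3. **Features** — starting glucose (last reading ≤10 min before the
   start), 15-min rate of change classified as falling (<−0.05
   mmol l⁻¹ min⁻¹), stable (±0.05) or rising (>0.05); insulin on board by
   linear decay with a 4-h duration of insulin action, normalised per kg;
   time since last bolus (<1.5 h / 1.5–3.5 h / >3.5 h); exercise duration,
   type (aerobic/anaerobic/mixed), intensity (Borg 6–20 mapped to
   light/moderate/vigorous at <12 / 12–14 / >14), time of day; participant
   demographics; and standard glycaemic metrics (mean, SD, CV, time in
   range) over the pre-exercise hour. Missing values are filled by k-nearest
   neighbour imputation (k=5), fitted on training folds only.
4. **Model** — an XGBoost classifier under participant-grouped stratified
   10-fold cross-validation (a participant's bouts never straddle folds),
   with a seeded budgeted hyperparameter search, greedy forward feature
   selection by mean CV ROC AUC, Youden-J thresholding for
   sensitivity/specificity, and fold-ensemble mean predictions (±95% CI)
   for external cohorts.
5. **Evaluation** — calibration curves, subgroup observed-vs-predicted
   rates with mean signed deviation (MSD), and an external-validation
   harness.
6. **Heatmap** — the simplified three-variable model (starting glucose,
   planned duration, falling-trend indicator) scored over a
   (glucose × duration) grid, one panel per trend class, with risk binned
   as very low (<1%), low (1–5%), moderate (5–20%) and high (>20%).

Real study datasets of this kind are access-controlled, so the package
ships a first-class synthetic cohort generator with a *known*
hypoglycaemia-generating process (mean-reverting AR(1) glucose with
exercise-, insulin- and trend-driven drift), making every stage testable
offline — including calibration checks against the generator's exact
conditional risk.

## Worked example

```python
from exhypo import simulate, pipeline, model, heatmap
from exhypo.features import SIMPLIFIED_FEATURES

cfg = simulate.SimConfig(n_participants=60, days=14, seed=7)
cohort = simulate.simulate_cohort(cfg)
table, qc = pipeline.preprocess(cohort.participants, cohort.series,
                                cohort.boluses, cohort.bouts)
print(f"included bouts: {len(table)}  hypo rate: {100*table['label'].mean():.1f}%")

plan = model.make_folds(table, k=10, seed=7)
ens = model.train_cv(table, plan, SIMPLIFIED_FEATURES, seed=7)
print(f"CV ROC AUC: {ens.auc_mean:.3f} (95% CI {ens.auc_ci[0]:.3f}, {ens.auc_ci[1]:.3f})")

grid = heatmap.build_grid(ens)
cell = grid.cells.query("glucose == 5.0 and duration == 30 and panel == 'falling'").iloc[0]
print(f"falling panel, 5.0 mmol/l, 30 min -> p = {cell.probability:.2f} ({cell.category})")
```

prints

```
included bouts: 1068  hypo rate: 11.0%
CV ROC AUC: 0.947 (95% CI 0.934, 0.960)
falling panel, 5.0 mmol/l, 30 min -> p = 0.84 (high)
```

A bout started at 5.0 mmol/l with glucose falling carries a predicted 84%
chance of dipping below 3.9 mmol/l within a 30-min session (red cell);
the same session started at 9.0 mmol/l with stable glucose sits in the
dark-green <1% band.

The same stages are available from the shell:

```bash
exhypo simulate   --out data/ --seed 7 --n-participants 60 --days 14
exhypo preprocess --data data/ --out prep/
exhypo train      --features prep/features.csv --out model/ --seed 7
exhypo select     --features prep/features.csv --out sel/trajectory.csv --max-steps 3
exhypo heatmap    --model model/ --out fig/risk_grid
```

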