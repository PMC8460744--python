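# realgait

Real-world gait speed from wrist acceleration — a tested, reusable
re-implementation of a cohort-scale analysis pipeline for epidemiologists
and movement scientists working with wrist-worn accelerometers.

Gait speed measured in daily life (not in a walking-lab corridor) is a
sensitive marker of functional decline. This package implements the full
chain from raw 50 Hz tri-axial wrist acceleration (±8 g) to
clinically usable speed metrics and their association with frailty and
muscle strength:

1. **Signal enhancement & features** — the acceleration norm is band-pass
   filtered (0.25–10 Hz) to remove gravity; per-second features are
   extracted: *intensity*, *periodicity*, *posture*, *noisiness* for
   detection, and *energy*, *step frequency*, *mean acceleration*,
   *wrist-swing power* for speed.
2. **Gait-bout detection** — a Gaussian (naive) Bayes classifier labels
   each second gait/non-gait, followed by two post-classification blocks
   (gap filling ≤ 2 s, then deletion of runs < 5 s); maximal gait runs
   become bouts.
3. **Speed estimation** — a single non-personalized linear regression
   maps the per-second speed features to instantaneous walking speed
   `v̂ₜ = β₀ + βᵀxₜ` (m/s), clipped to [0.1, 4] m/s.
4. **Speed metrics** — bouts are stratified by duration (SHORT < 30 s,
   MEDIUM 30–120 s, LONG > 120 s); per subject and category the speed
   distribution is summarized by mode (the *preferred speed*, the peak of
   a Silverman-bandwidth Gaussian KDE), median, mean, 75th/90th/95th
   percentiles, SD and maximum.
5. **Clinical scores** — the weakness-based Fried frailty proxy
   (sex-specific, BMI-stratified handgrip cutoffs), BMI / age / physical
   activity categories, best-of-three grip.
6. **Association analysis** — nested models A (sex + age group + BMI
   category + PA level) vs. B (A + one speed metric): logistic for
   frailty with AUC, linear for grip with adjusted R²; compared by the
   likelihood-ratio test, AIC = 2k − 2ℓ and BIC = k ln n − 2ℓ; forward
   stepwise selection (entry p < 0.05); sensitivity analyses excluding
   probable runners and restricting to ages 65+.

Because cohort accelerometry data of this kind is not publicly
depositable, the package ships a **synthetic cohort generator** with full
ground truth at two fidelities — per-second speeds from activity
schedules for thousands of subjects ("metric level"), and raw wrist
signals with arm-swing/step harmonics for small detector benchmarks
("signal level"). Every downstream stage is tested end to end against
this generator.

## Worked example

```python
from realgait.pipeline import metric_cohort_pipeline
from realgait.association_analysis import run_frailty_analysis, run_grip_analysis

table = metric_cohort_pipeline(n=2000, n_days=13, seed=42)
print(len(table), int(table.frail.sum()))          # 2000 subjects, 178 frail
print(table["mode_all"].median())                  # 1.47 m/s preferred speed

rep = run_frailty_analysis(table)
row = rep[(rep.duration == "medium") & (rep.metric == "p95")].iloc[0]
```

On this simulated cohort the run prints a median preferred speed of
1.47 m/s (inside the 1–1.6 m/s normative band) and, for the 95th
percentile of speed in 30–120 s bouts: frailty model A AUC 0.785 → model
B AUC 0.787 (LR 5.1, p 0.024, AIC 1026.4 → 1023.4) and grip adjusted R²
0.621 → 0.623 (LR 11.6, p 0.00066). Adding the speed metric improves
both models because, in the generator as in real cohorts, walking speed
and grip strength share an age-related decline; the effect on frailty is
modest at this sample size and effect scale.

A command-line interface mirrors the pipeline stages:

```bash
realgait simulate --n 200 --days 13 --fidelity metric --seed 1 --out-dir runs/demo
realgait analyze  --cohort runs/demo/cohort_metrics.csv --out-dir runs/demo
realgait run      --config config.yaml --out-dir runs/full   # end-to-end, checksummed
```

## Layout

```
src/realgait/
  synthetic_data.py      cohort, schedule and raw-signal generators
  signal_features.py     enhancement + per-second feature extraction
  bout_detection.py      Bayes classifier, smoothing, bouts, scoring
  speed_estimation.py    per-second speed regression and RMSE
  speed_metrics.py       duration categories, KDE mode, metric set
  clinical_scores.py     frailty rule, BMI/age/PA categories, grip
  association_analysis.py nested models, LR/AUC/AIC/BIC, stepwise
  pipeline.py            end-to-end orchestration, seeded stages
  cli.py                 `realgait` command group
docs/methods.md          model assumptions, parameters, limitations
```
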