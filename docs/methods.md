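# Methods

This note documents the models, parameter choices and limitations of the
`realgait` pipeline and its synthetic data generator.

## The synthetic cohort

No public raw-accelerometry cohort with per-second gait ground truth is
available, so all calibration and benchmarking runs on a simulated
community-dwelling cohort. The generator's defaults describe the study
conditions and are not tuning knobs:

**Covariates.** 53.7% women; age drawn in four decadal groups with
weights 29.6 / 32.4 / 25.9 / 12.1% spanning 45–86 y; BMI in three
classes (41.2 / 40.6 / 18.2% normal / overweight / obese); 38.8%
physically active (≥ 150 min/week MVPA).

**Preferred walking speed** (m/s) is linear in the covariates:
`1.38 + 0.08·man − 0.009·(age − 62) − 0.012·(BMI − 26) + 0.10·active + ε`,
ε ~ N(0, 0.10), clipped to (0.5, 2.1). The resulting cohort median is
≈ 1.45 m/s, inside the 1–1.6 m/s normative band for usual gait speed,
with the expected declines by age and BMI.

**Grip strength** (kg) is linear in sex, age and preferred speed:
base 43 (men) / 26 (women), −0.25 kg/y, +6 kg per m/s of preferred
speed, with sex-specific noise SD 8.5 / 5.5 kg. These intercepts and SDs
were chosen so that (a) the pooled grip distribution is ≈ 34 ± 12 kg and
(b) applying the weakness-based frailty rule to the generated
(sex, BMI, grip) yields a frail prevalence near the 9.2% target — the
rule itself is never overridden. At n = 2809 the generator produces
9.3% frail and grip 34.8 ± 11.8 kg.

**Daily schedules.** Each day holds an inactive night and morning /
afternoon active windows (plus occasional evening bouts), with on average
25 gait bouts/day. Bout durations come from a 65 / 30 / 5% mixture:
short uniform on 5–29 s, medium uniform on 30–120 s, long
121 s + Exp(80 s) capped at 600 s. Per-bout mean speed is
N(preferred, σ_w) with σ_w ~ U(0.06, 0.14) m/s per subject, inflated
×1.8 for long bouts (long outdoor bouts vary more); within a bout,
speeds get an AR(1) jitter (ρ = 0.7) with SD 0.4·σ_w, so a subject with
σ_w = 0 walks exactly at their preferred speed. ~25 bouts × ~41 s mean
duration ≈ 17 min of gait per day; this is at the low end of free-living
walking time, chosen so that cohort-scale simulation stays cheap while
every per-subject metric still rests on thousands of gait seconds.

**Raw signal model** (signal fidelity). The device-frame gravity vector
has a polar angle depending on activity (≈ 75° during gait — forearm
hanging, ≈ 40° in other activity, ≈ 10° at rest) with a slow ±3°
wobble. Gait adds, along the gravity axis, a step-impact harmonic at the
step frequency `f = 1.45 + 0.35·v` Hz with amplitude 0.30 + 0.18·v g and
an arm-swing component at f/2 at half that amplitude; non-gait activity
adds aperiodic 0.3–3 Hz band-limited noise (0.15 g rms); white sensor
noise (0.03 g per axis) is always present; samples are clipped at ±8 g.
The affine cadence–speed law and the amplitudes are configurable
(`SignalConfig`): published wrist studies motivate the form, but not
specific constants, of this model.

Benchmark recordings compress a day to 4 active hours (~60 bouts,
~40 non-gait events) so that a 40-subject detector/speed benchmark runs
in about a minute and a half.

## Feature definitions

The four detection features and four speed features are named, but not
defined, in the wrist-accelerometry literature this pipeline follows;
the concrete definitions here are this package's contract (all
per-second, with a 5 s centered context window for spectral and
autocorrelation quantities; edge seconds use a truncated window and are
flagged):

* intensity — SD of the enhanced norm within the second;
* periodicity — maximum normalized autocorrelation of the context
  window over lags 0.25–2 s (clipped to [0, 1]);
* posture — angle between the context-window mean raw vector (a proxy
  for the < 0.25 Hz gravity component) and the +z reference axis;
* noisiness — fraction of context spectral power above 4 Hz within
  0.1–10 Hz;
* energy — mean squared enhanced norm within the second;
* step frequency — the spectral peak in 1.0–3.5 Hz, accepted only when
  it is ≥ 8× the mean band power, refined to sub-bin resolution by
  zero-padded FFT (1024 points) plus parabolic interpolation of the
  log-power peak; otherwise flagged undefined (such seconds are never
  assigned a regression speed — they inherit the bout's median);
* mean acceleration — mean raw norm within the second;
* swing — band power in [f/2 ± 0.25] Hz.

The sub-bin peak refinement matters: a plain 5 s window quantizes
frequency at 0.2 Hz, which through the cadence–speed relation would
alone contribute ≈ 0.16 m/s of speed error — above the 0.10 m/s
benchmark ceiling. With refinement the cadence-implied speed error is
≈ 0.02 m/s.

## Detection and speed models

The "Bayes classifier" is implemented as diagonal-covariance Gaussian
naive Bayes (the minimal reading), trained on class means/variances with
priors equal to class frequencies; posterior ties resolve to non-gait
(conservative). The implementation is a dozen lines of explicit
log-posterior algebra and is cross-checked against scikit-learn's
`GaussianNB` in the test suite. The two post-classification blocks are
gap filling (non-gait runs ≤ 2 s flanked by gait) followed by short-run
deletion (< 5 s), in that order; the composition is idempotent.

The speed model is one pooled OLS regression (never refit per subject)
of true speed on the four speed features, fit on training subjects only;
predictions are clipped to [0.1, 4] m/s.

## Speed metrics

Pooling is duration-weighted: the sample unit is the gait second, so a
120 s bout contributes 120 samples. This matches the estimator's native
per-second output; a per-bout-mean mode exists behind a flag for
sensitivity checks. Percentiles use linear interpolation between order
statistics; SD uses n − 1. The preferred speed is the argmax, over a
fixed grid 0–4 m/s in 0.01 steps, of a Gaussian KDE with Silverman
bandwidth; ties break to the lowest speed, and categories with fewer
than 10 gait seconds are marked missing. For cohort-scale speed the KDE
is evaluated by linear binning onto the grid followed by convolution
with the Gaussian kernel — equivalent to the direct kernel sum on this
grid (the bandwidth always spans several grid steps; equivalence to
`scipy.stats.gaussian_kde` is asserted in the tests) and O(n) rather
than O(n·grid).

A calendar day (multiples of 86 400 s from recording start; no time-zone
logic) is *valid* if at least one bout starts in it; subjects with no
valid days are excluded as having no walking-speed data.

## Association layer

Base covariates enter dummy-coded with the first level as reference;
age enters as the printed categorical groups, not continuously. Dummy
columns for levels absent from a subset (e.g. the younger groups in the
65+ sensitivity analysis) are dropped to keep the design full rank.
Logistic fits use Newton iterations to tolerance 1e-8; diverging
coefficients or non-convergence raise a separation error, and in the
report tables a fit that cannot be computed on a subset yields an NaN
row rather than aborting. AUC is in-sample (no cross-validation),
computed by the rank (Mann–Whitney) formulation with average-rank tie
handling. For linear models the Gaussian profile log-likelihood feeds
AIC/BIC with k = number of mean parameters. The stepwise entry test is
the LR test with p_entry = 0.05, ties broken by candidate order.
Reports flag significance at both 0.05 and the stricter 0.001 headline
level appropriate when 8 metrics × 3 duration categories are tested.

The runner-exclusion threshold defaults to 2.5 m/s on the all-bout 95th
percentile. Note that the default generator produces no running
(bout speeds are capped at 2.4 m/s), so on synthetic cohorts this
filter excludes nobody; the operation is exercised against a
direct-count oracle at lower thresholds.

Calibration tests of the inference layer (type-I error, power,
coefficient recovery) use a separate direct generative model in which
frailty follows a known logistic law and the candidate metric is
independent of the base covariates. This is deliberate: in the main
generator frailty is produced by the grip rule and grip is coupled to
walking speed, so speed metrics are *truly* associated with frailty
there and no exact null exists.

## Problem sizes

Default test and benchmark sizes: metric-fidelity calibration at
n = 2000 × 13 days; detector/speed benchmark at 40 subjects × 4 h with a
20/20 subject split; type-I error at 1000 replicates of n = 2000; power
at 100 replicates; stepwise null at 200 replicates. These sizes give
Monte-Carlo error well inside the asserted tolerances (e.g. binomial SE
0.7 points on a 5% rejection rate at 1000 replicates).

## Known limitations

* The synthetic signal is far cleaner than real free-living wrist data:
  no non-wear, no device undocking, no sleep/wake ambiguity, no
  transport vibration, no cycling or stair climbing, and gait harmonics
  with stable amplitudes. Detector performance on it (near-perfect on
  held-out subjects) therefore demonstrates correctness of the pipeline
  mechanics, not real-world accuracy; the reported floors
  (sensitivity 90.2%, specificity 97.2%, RMSE 0.10 m/s) should be read
  as the operating point the real algorithms achieve on real data, which
  the synthetic benchmark must at least match.
* Walking and running are not distinguished; running appears only
  through the exclusion-style sensitivity analysis.
* Handedness (device on the dominant wrist) is not modeled.
* Missing data are handled by complete-case analysis only; the frailty
  proxy uses grip weakness alone, not the full five-criterion phenotype.
* Associations estimated on the synthetic cohort arise from the
  generator's explicit couplings and carry no epidemiological meaning.
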