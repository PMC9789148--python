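# gaitpain

Gait analysis from wearable trunk accelerometry and its association with
mild unilateral knee pain while walking.

People with early knee osteoarthritis often report mild pain during
walking long before radiographs show much damage. Inertial sensors worn
during a short over-ground walk yield a rich panel of gait parameters —
spatiotemporal measures, left/right symmetry, stride-to-stride
variability, signal complexity — and the question for an epidemiologist is
which of these measures, if any, track the presence of mild unilateral
pain once age, sex, body mass, depressive symptoms and radiographic
disease are accounted for. This package implements that full analysis
chain for biostatisticians and movement scientists, together with a
synthetic-data generator with known ground truth so that every stage can
be validated end to end without any participant data.

## What it computes

**Gait parameters** from a vertical trunk-acceleration trial (plus
per-side heel-strike/toe-off events, detected or annotated):

- spatiotemporal: gait speed = distance/time, cadence (steps/min),
  step length, stride/stance/swing times and cycle percentages per side;
- symmetry: step and stride regularity — the unbiased autocorrelation
  of the trace at the mean step and stride lags — their ratio (step
  symmetry, 1 = symmetric), and swing-time gait asymmetry
  `GA = 100·|ln(SwR/SwL)|` (0 = perfect symmetry);
- variability: stride-time and stance-time coefficients of variation
  (100·sd/mean), and the phase coordination index
  `PCI = CV(φ) + 100·mean|φ−180°|/180°` for the left–right step phase φ;
- complexity: sample entropy `−ln(A/B)` (template matches of length
  m+1 over length m, Chebyshev distance, r = 0.2·sd) and the short-term
  largest Lyapunov exponent by Rosenstein nearest-neighbour divergence;
- spectral: dominant frequency in the 0.5–3 Hz walking band of the Welch
  power spectral density, its amplitude and half-power width.

Two trials per participant are averaged, and participants with gait speed
outside 0.3–2.3 m/s are excluded as invalid measurements.

**Cohort construction**: per-person pain outcomes from per-knee ratings
(bilateral pain excluded; mild unilateral vs no pain as the binary
outcome; a 3-category outcome keeps the moderate/severe group), a
radiographic OA count (knees with Kellgren–Lawrence grade ≥ 2, missing
current grades back-filled from the most recent prior exam), and a
standardized analysis table.

**Variable selection**: a resampled super learner. Each run imputes
missing values by chained equations, splits 70/30 stratified on the
outcome, fits a convex stack of base learners (lasso/ridge/elastic-net
and plain logistic regression, random forest, gradient-boosted trees,
SVM; weights minimise fivefold cross-validated squared-error loss), and
flags variables whose permutation importance on the test set exceeds a
noise cutoff. Variables are ranked by the percentage of runs flagged;
the top 10 go forward, and test AUCs are summarised by their median and
2.5–97.5th percentiles.

**Association models**: unadjusted (gait variables jointly as the
exposure) and adjusted logistic regression — `aOR = exp(β)` per sd with
Wald 95% CIs — with collinearity screening (pairwise |r| > 0.80,
tolerance < 0.10, VIF > 10, eigenvalue/condition indices), a
proportional-odds check for the 3-category outcome, a generalized-logit
multinomial sensitivity model, and a gait-speed < 1.8 m/s sensitivity
restriction.

## Worked example

`examples/04_association_models.py` generates a 2500-person cohort whose
mild-pain outcome carries a per-sd odds ratio of 0.8 on step regularity,
plus a gait-speed effect confined to the moderate/severe category, and
fits the models:

```
adjusted model (mild unilateral pain vs no pain), OR per sd:
       variable  odds_ratio  ci_low  ci_high
step_regularity       0.767   0.693    0.848
 sample_entropy       1.055   0.954    1.166
     gait_speed       1.048   0.948    1.160

collinearity flags: none
max VIF 2.61, min tolerance 0.384

proportional odds: p = 0.0000 -> generalized_logit

gait speed by contrast (generalized logit):
         contrast  odds_ratio  ci_low  ci_high
  mild_vs_no_pain       1.051   0.949    1.163
modsev_vs_no_pain       0.554   0.479    0.640
```

The adjusted CI for step regularity covers the generative value 0.8; the
null variables' CIs cover 1; and the planted severity-specific speed
effect appears only in the moderate/severe contrast, which is why the
proportional-odds assumption is rejected and the generalized logit is
used. The other examples cover signal-level feature extraction
(`01`), outcome construction (`02`), the selection loop (`03`) and the
full pipeline with its reproducible report bundle (`05`). The pipeline is
also scriptable: `gaitpain run --config pipeline.yaml --seed 7`.

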