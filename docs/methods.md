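# Methods

This note records the models, the constants that matter, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and gait events

A walking trial is modelled as vertical trunk acceleration. The
synthetic generator writes

    a(t) = 1 g + Σ_k A_k · exp(−(t − t_k)² / 2σ²) + ε(t),

a train of Gaussian-windowed heel-strike impulses on a gravity baseline
with additive white noise. Step times t_k form a renewal process with
mean interval 60/cadence and a configurable coefficient of variation;
amplitudes alternate between sides by the left/right ratio (1 =
symmetric); σ is 10% of the mean step interval. Toe-offs sit one swing
time before the next ipsilateral strike. The generator returns its exact
event times so that downstream code is validated against ground truth
rather than against its own detector. Default sampling rate is 100 Hz
and default trial distance 20 m — declared defaults, since walk-test
hardware rates vary.

This model deliberately exposes the contrasts the features measure
(regularity, symmetry, variability, periodicity) and deliberately omits
much of real trunk accelerometry: no triaxial content, no turning or
gait initiation/termination transients, no soft-tissue artifact, no
drift. Passing tests therefore demonstrate the correctness of the
feature definitions and the pipeline contracts, not robustness to every
artifact of field recordings.

Event detection band-passes the trace to 0.5–3 Hz (4th-order
Butterworth, zero-phase), takes prominent local maxima at least 0.25 s
apart as heel strikes, and assigns sides by strict alternation starting
from the trial's configured first side — a single trunk sensor cannot
identify sides, so the convention must come from metadata (default
"left"). Without ankle annotations, toe-offs are estimated as the
contralateral strike plus one double-support interval (default 10% of
the stride); annotated events are used verbatim when provided.

## Feature definitions and numerical choices

- Regularity: unbiased autocovariance of the demeaned trace normalised
  to lag 0; step (stride) regularity is the maximum within ±25% of the
  mean step (stride) lag. Step symmetry is their ratio; the "symmetry of
  acceleration between limbs" wording in the field does not pin a
  formula, so the ratio convention (1 = symmetric) is used and declared.
- CVs use the sample standard deviation (ddof = 1), in percent.
- Phase coordination uses left-leg strides containing exactly one right
  strike; strides without one are skipped, and more than 50% skipped
  marks the value undefined.
- Sample entropy: m = 2, r = 0.2·sd, Chebyshev distance, self-matches
  excluded, both template counts over the first N−m windows. In the
  trial pipeline it is computed on the band-passed trace resampled to
  50 Hz; series and (m, r) are field-standard defaults, declared in
  `FeatureConfig`.
- Spectral features: Welch periodograms, Hann window, 5 s segments, 50%
  overlap (0.2 Hz bins at 100 Hz); the peak is searched in 0.5–3 Hz and
  its width measured at half power with linear interpolation, clipped to
  the band.
- Lyapunov exponent: Rosenstein nearest-neighbour divergence. The trial
  wrapper embeds the band-passed trace in dimension 5 with delay at the
  first autocorrelation zero crossing, excludes neighbours within one
  stride in time, fits the mean log-divergence over 0–0.5 stride, and
  reports per second; at least 30 s of signal is required, so short walk
  tests legitimately yield a missing value. Initial neighbour distances
  at machine precision (exact repeats of a noiseless periodic orbit) are
  excluded: their logs drift randomly and carry no dynamical
  information. Sanity checks on discrete series (the chaotic logistic
  map, whose exponent is ln 2 per iteration, and a sampled periodic
  signal) use the per-step convention of the underlying estimator.
- Undefined feature values propagate as NaN; trial averaging is the
  element-wise mean over defined values, and wholly-undefined features
  are later either dropped (if empty for everyone) or imputed.

Speed validity keeps 0.3–2.3 m/s by default; 1.8 m/s as the upper bound
reproduces the fast-walker sensitivity restriction.

## Cohort rules

Bilateral walking pain excludes a participant (the analysis targets
asymmetric gait change); exactly one painful knee defines the unilateral
outcome at that knee's severity; "extreme" is grouped with
moderate/severe (configurable). The binary outcome is missing for the
moderate/severe group. The radiographic OA count back-fills a missing
current KL grade from the most recent prior non-missing exam and never
overwrites an observed grade; a knee with a total replacement is treated
as missing-and-back-filled, since such knees stop being radiographed.
Continuous variables are z-scored over the assembled analysis sample
(the ML stage refits internally on training data; the regression stage
uses the shared standardization). CES-D is treated as continuous.

## Selection loop

Per run: (1) single chained-equations completion of the candidate table
— linear conditionals with Gaussian residual noise for continuous
columns, multinomial-logistic conditionals with probability sampling for
categorical ones, 5 cycles, seeded; rows with a missing outcome are
dropped first and the outcome is not an imputation predictor; (2)
stratified 70/30 split; (3) super learner: every base learner fit per
fold of a fivefold stratified CV, meta-weights solved on the probability
simplex by SLSQP to minimise out-of-fold squared error (so the stack's
CV loss cannot exceed any single learner's by more than optimiser
tolerance), then base learners refit on the full training set; (4)
permutation importance on the test set — mean increase in squared-error
loss over seeded permutations, variables processed in name order so
column order is irrelevant.

"Influential" per run was an open design point. A variable is flagged
when its importance exceeds both (a) the 95th percentile of the
magnitudes of the negative importances (sign-flipped permutation noise)
and (b) 1% of the baseline test loss. The floor exists because any
finite dataset carries some chance association that re-splitting cannot
remove; a null calibration (n = 2000, ~30 candidates) put the per-run
maximum noise importance at 0.2–0.7% of baseline loss while a per-sd
odds ratio of 0.8 scores 0.7–2.1%, so 1% suppresses chance flags while
leaving weak real effects detectable at above-chance frequency.

Two registry profiles exist: `desk` (lasso, random forest,
gradient-boosted trees — the default used throughout the tests) and
`full` (adds ridge, elastic net, plain logistic, SVM). Bayesian additive
regression trees have no implementation available, so the registry drops
that entry with a logged notice; the stack's contract does not depend on
any single learner. Aggregation takes the top 10 variables by cross-run
frequency (ties by mean importance, then name) and reports the median
test AUC with its 2.5–97.5th percentile interval.

## Association models

Logistic regression by maximum likelihood; ORs are exp(coefficients)
with Wald 95% CIs (profile likelihood was considered and left out; Wald
is the default convention when a CI method is unstated). The unadjusted
model contains the selected gait variables jointly — they are the
exposure of interest — and the adjusted model always adds age, sex,
race/site, BMI, CES-D and the OA count, selected or not, since they are
established confounders. Categorical covariates use reference-cell
(first-level) coding; the OA count is entered as a count. Rows with
missing model variables are dropped listwise (imputation serves only the
selection stage). Collinearity screening flags |r| > 0.80,
tolerance < 0.10 and VIF > 10, reports eigenvalues and condition indices
of the predictor correlation matrix, and recommends greedy drops
(highest VIF first) until no threshold fires; the pipeline applies the
drops to the gait exposures only. This matters in practice: cycle
percentages sum to 100 per side, and cadence determines stride time, so
an unscreened selected set can be exactly singular.

The 3-category sensitivity analysis first compares a cumulative-logit
proportional-odds fit against the generalized-logit fit by a chi-square
on twice the log-likelihood gap with one degree of freedom per extra
slope (simulation places the type-I rate near nominal and power against
strongly divergent category slopes near 1), then reports both contrasts
(mild vs none, moderate/severe vs none) from the generalized logit with
"no pain" as reference.

## Pipeline and reproducibility

The pipeline couples the two generators: each synthetic participant's
trials are synthesised from that participant's drawn gait parameters
(speed fixes trial duration, cadence the step interval, stride-time CV
the interval spread, swing times the toe-offs), so extraction applied to
the raw traces recovers the values the outcome was generated from and
known effects survive the whole chain. All stage outputs are plain CSV/
JSON; a manifest records seed, config and its hash; identical config and
seed reproduce the bundle byte for byte. Every random draw descends from
the single configured seed via spawned seed sequences.

Desk-scale problem sizes used by the test suite — cohorts of 100–2500,
4–10 selection runs, 3 base learners, 50-replicate recovery simulations
— are the package's validation profile; the full 100-run, 7-learner
configuration is available through `PipelineConfig`/`run_selection_loop`
arguments.

## Known limitations

- The signal generator's impulse-train gait is far cleaner than field
  accelerometry; detector tolerances (peak prominence 0.5 sd, minimum
  step interval 0.25 s) have been validated only against it.
- Side assignment by alternation fails silently on missed steps; with
  ankle-sensor event annotations this path is bypassed.
- Missingness is MCAR only; imputation under MAR/MNAR mechanisms is out
  of scope.
- The multinomial/proportional-odds comparison treats the generalized
  logit as the encompassing model; the two families are not strictly
  nested, and the chi-square reference is an approximation (its
  simulated size is checked in the tests).
- Permutation importance shares credit among correlated variables;
  frequencies for near-duplicate measures (e.g. cycle percentages)
  should be read jointly, not per variable.
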