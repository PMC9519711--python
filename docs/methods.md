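# Methods

`csdhval` validates published prognostic models for chronic subdural
hematoma (CSDH) outcomes on patient-level cohorts. This note records the
statistical procedures, the defaults and why they were chosen, the design
choices made where the problem left the design open, and what the synthetic
data can and cannot demonstrate.

## Model representation and evaluation

A published model is data, not code: a `ModelSpec` holds predictor
categorization rules (numeric thresholds with explicit boundary ownership,
named category groups, or a continuous nomogram axis), per-category points,
and a risk map from total score/points to probability. This keeps the
arithmetic engine testable independently of any particular model's numbers
and means transcription errors are confined to the definition files.

Boundary ownership is encoded explicitly because published categorizations
genuinely differ: the SHE score splits age as `< 80 / >= 80` while the Jack
score uses `<= 80 / > 80`, so a patient aged exactly 80 falls in different
categories under the two models. Both encodings are preserved as published
and pinned by unit tests. Categories must tile the predictor's domain with
each cut point owned by exactly one side; gaps and overlaps are load-time
errors.

Nomogram axes are read the way a person reads a nomogram: piecewise-linear
interpolation between tabulated anchors, clamped at the extremes (no
invented tail behavior). Score tables are exact integer lookups; a total
score outside the table is a domain error rather than silent extrapolation.
Risk maps must be monotone non-decreasing with probabilities strictly inside
(0, 1). Probabilities are clipped into `[1e-6, 1 - 1e-6]` before the logit
so degenerate maps still yield finite linear predictors; the clip bound is a
documented module constant (`PROB_CLIP`).

The shipped model files carry the published predictor categorizations but
*synthetic placeholder* point values and risk maps (their filenames say so):
the numeric tables appear only in the development publications, and
transcribing wrong numbers silently would be worse than shipping labelled
placeholders.

## Derived predictors and outcomes

* Hematoma volume from three orthogonal diameters: `a*b*c/2` (mL with cm
  inputs).
* Septations are read off the hematoma-type label: present for
  membranous/trabecular hematomas, absent for the other *named* types.
  Unknown labels and missing types propagate as missing — the rule only
  covers named types, so anything else must not silently become "no
  septations".
* Outcome windows: 30-day mortality with day 30 inclusive; recurrence
  (retreatment by reoperation or renewed dexamethasone) within 61 days
  (2 months) and 92 days (3 months). Month lengths are conventions, so they
  are module constants (`DAYS_2M`, `DAYS_3M`) rather than buried literals;
  2-month recurrence implies 3-month recurrence by construction and by
  property test.
* Only unilateral-hematoma records enter analysis sets (the validated
  models were developed for unilateral CSDH); bilateral records survive in
  the raw table but are filtered at selection.

Analysis sets come in two modes. *Complete case*: all of the model's
predictors and its outcome observed. *Imputed*: outcome observed, missing
predictors left to multiple imputation. Outcome-missing records are dropped
in both modes and never imputed. An empty selection raises an explicit
error that the pipeline records as a failed cell instead of propagating a
zero-division downstream.

## Performance statistics

All logistic fits are maximum likelihood via statsmodels GLM (binomial
family, IRLS) with Wald 95% intervals from the information matrix. IRLS and
Newton–Raphson converge to the same MLE here; statsmodels is the standard,
battle-tested fitter, so the package does not hand-roll its own. Fits whose
coefficients exceed 50 in absolute value (or fail to stay finite) are
reported as estimation errors — at that magnitude the data are separated
for practical purposes. Degenerate inputs fail loudly: all-event or
all-non-event outcome vectors, and a constant linear predictor for the
slope model.

* **Calibration intercept**: offset-logistic model
  `logit Pr(y=1) = a + lp`, slope fixed at 1 by entering `lp` as offset.
  With constant predictions this has the closed form
  `a = logit(mean y) − lp`, which the tests pin.
* **Calibration slope**: `logit Pr(y=1) = alpha + b·lp`.
* **C-index**: computed from mid-ranks, which is algebraically identical to
  counting concordant pairs with 0.5 credit for ties (the standard
  convention); verified against O(n²) pair counting. The CI is a seeded
  nonparametric percentile bootstrap, 2000 replicates by default —
  assumption-free and reproducible; resamples with no events or no
  non-events carry no information and are skipped (an error is raised if
  too few informative resamples remain). The bootstrap SD of logit(C) is
  retained for pooling.
* **Model-based concordance**: computed with an O(n log n) sorted
  prefix-sum algorithm; the pairwise definition (concordant mass
  `p_i(1−p_j)` for `p_i > p_j`, half the informative mass for ties,
  denominator `p_i(1−p_j)+p_j(1−p_i)`) is the test oracle, matched to
  1e−12. All-tied predictions return exactly 0.5. mbc is deliberately *not*
  invariant under monotone transforms of p (unlike C) — a property test
  asserts both facts.
* **Calibration curves**: equal-count bins (`np.array_split` over the risk
  ordering, so 10 bins on n = 1000 hold exactly 100 each) with a
  reduced-bin fallback flag when distinct predictions are scarcer than
  bins; or a lowess smoother, default span 0.75 (the choice of smoother is
  a convention; it is configurable).

## Multiple imputation and pooling

Chained equations via statsmodels `MICEData`: each incomplete variable is
regressed on all others and imputed by predictive mean matching (PMM, 5
donors) with Bayesian ("gaussian") parameter perturbation. PMM is used for
*all* variable kinds — binary and unordered categorical variables enter as
integer codes — because PMM only ever returns observed donor values, so
imputed categories are automatically in-domain without per-type logistic or
multinomial conditionals. The cost is that categorical codes act as ordinal
covariates inside other variables' conditional models; for the short,
roughly severity-ordered categorical scales here that is an acceptable
approximation, and it buys a single well-tested imputation engine.

Hospital region joins every conditional model as fully observed indicator
columns and is itself never imputed; a variable collected nowhere in one
region is therefore imputed from the other regions' records (a variable
observed nowhere at all is an explicit error). Outcome columns may serve as
predictors of missing covariates but are never imputed — the imputer
refuses cohorts whose outcome column still has holes, since outcome-missing
records must be dropped upstream. Defaults: m = 10 imputations, 10 chain
iterations, independent chains with sub-seeds spawned from one seed; the
chain seeds drive NumPy's global generator (which `MICEData` uses
internally), and the previous global state is restored afterwards. Observed
cells are checksum-verified unchanged after every run.

Rubin's rules: pooled estimate = mean; total variance
`T = W + (1 + 1/m) B`; CI from the t-distribution with Barnard–Rubin
degrees of freedom when a complete-data df is supplied, classic
`(m−1)/λ²` otherwise; `B = 0` degenerates to a normal interval with
`T = W`. Intercept and slope pool on their natural coefficient scale. The
C-index pools on the log-odds scale (per-imputation bootstrap variance of
logit C), then back-transforms — bounded statistics pool better on an
unbounded scale. mbc is a function of predictions only, so it is averaged
across imputations. The per-imputation bootstrap variance entering Rubin's
rules is a pragmatic simplification (it ignores interaction between
resampling and imputation uncertainty) and is documented as such.

## Synthetic cohorts

The generator emulates the marginal structure of a three-region Dutch CSDH
registry of unilateral patients: region shares 10.6/54.7/34.7%, 73.5% male,
age truncated-normal with mean 73.0 (SD 12.4) on [18, 105], volume
truncated-normal with mean 112.6 (SD 54.5) on (0, ∞), plus the published
frequencies for GCS category (0.2/11.8/87.9%), septations (37.2%),
hypertension (16.1%), density, drainage time, drain type, treatment, and
postoperative complications (7.2%). Because truncation shifts the mean of a
plain truncated normal (volume is cut at zero only about two SDs below
center), the location parameter is solved numerically so the *realized*
mean matches the target. The rare GCS 3–4 category is kept at its tiny rate
on purpose: it exercises rare-category handling downstream.

Outcomes come from configurable logistic "true models"; the intercept is
solved by root bracketing so the expected prevalence hits the target
(defaults 3.9% mortality, 9.5% 3-month recurrence) to within the solver
tolerance. Two-month recurrence is a thinned subset of 3-month recurrence
at the registry's event-count ratio 155/164, which enforces nesting exactly.
The default coefficients are arbitrary documented experiment settings —
the registry's true predictor-outcome associations are unknowable from
published marginals, so recovery tests make claims about the *machinery*,
not about CSDH biology.

Missingness defaults mirror the registry's missing shares per column
(volume 46.6%, septations 48.8%, hypertension 22.9%, density 45.4%,
drainage time 56.9%, drain type 74.9%, complications 22.4%, GCS 6.5%),
masked MCAR and independently per column, with optional region-level
structural blanking and small outcome-availability gaps (5.9%/1.5%/1.5%)
that drop records from analysis rather than being imputed.

What the generator does *not* emulate: any dependence between predictors
(no published joint distribution exists; draws are independent, with the
single exception that hematoma type is drawn consistently with the
septations flag so the derivation rule holds), correlated or MNAR
missingness (the registry's missingness is plausibly clustered within
patients and regions; the default here is independent MCAR), auxiliary
imaging variables, and competing risks of death before recurrence.
Consequently, passing pipeline tests demonstrate correctness of the
statistical machinery under known data-generating processes — they do not
certify performance numbers on any real registry, whose case-mix,
predictor correlations, and missingness patterns differ.

## Simulation sizes used by the tests and acceptance script

Parameter-recovery runs use n = 100,000 (intercept within ±0.02 of 0,
slope within ±0.03 of 1, |C − mbc| ≤ 0.01) and n = 50,000 for injected
miscalibration (slope within ±0.1 of 2; offset intercept within ±0.05 of
−1.5) — sizes at which the Monte-Carlo standard errors sit comfortably
inside those tolerances. The MCAR agreement check runs at n = 5,000 with
m = 10 and 10 chain iterations; the slope-CI coverage check runs 50
repetitions at n = 1,000 with 5 chain iterations (coverage is a property of
the interval construction, not of n, so the repetitions are sized for
throughput). The end-to-end run uses a registry-sized cohort (n = 1,760),
m = 10, 5 chain iterations, and 100–200 bootstrap replicates. All
simulations are driven by explicit seeds.

## Known limitations

* The shipped model definitions carry placeholder risk tables (see above);
  validation output for them characterizes the pipeline, not the published
  models, until the real tables are transcribed.
* PMM-for-everything imputation treats coded categories as ordinal inside
  conditional models.
* The C-index CI under imputation combines bootstrap variance and Rubin's
  rules in the simplified way described above.
* Calibration-curve export under imputation uses per-record predictions
  averaged across completed datasets; a fully pooled curve would require
  pooling bin boundaries as well.
* The pipeline validates models as published; it does not update,
  recalibrate, or develop models.
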