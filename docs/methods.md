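# Methods

## Synthetic cohort generator

The generator (`advrisk.synthetic_cohort`) emulates the structure of a
mammography-registry screening cohort at the exam level. Each woman gets a
race/ethnicity group (five levels: Asian, Black, Hispanic, White,
Other/Multiple — all non-Hispanic except Hispanic), a screening interval
(annual/biennial), and covariates drawn from race-specific conditional
distributions: age piecewise-uniform on [40, 74] years, menopausal status,
first-degree family history, five-level benign-biopsy history, four-level
BI-RADS density, and five-level BMI category. Default marginal choices
follow the published characteristics of the BCSC screening cohort: race
mix ≈ 10/9.5/5/73.5/2%, annual share 77.2%, higher density and lower BMI
for Asian women, higher BMI for Black and Hispanic women, and item-level
missingness at the published magnitudes (BMI 34%, menopause 18%, family
history 3.7%, race 4.5%, biopsy and density 2%).

Outcomes follow the same model family the analysis fits, which makes
generated cohorts a parameter-recovery oracle. Per exam, the advanced-
cancer probability is `q = expit(lp_adv)` and, conditional on no advanced
cancer, the competing-event probability is `c = expit(lp_comp)`; each
linear predictor has a per-(menopause × interval) intercept, a raw
age + age² polynomial, and level effects. Default advanced-cancer effects:
race odds ratios 2.0 (Black), 0.7 (Asian), 1.2 (Other/Multiple) vs. White;
family history 1.5; biopsy 1.4–2.2; density 0.5–1.6 vs. scattered; BMI
0.8–1.5 vs. normal.

**Inflated event rates.** Real per-exam advanced-cancer rates are
0.03–0.16%; at desk scale (a few 10⁵ exams) this leaves too few events for
stable stratified fits with ~26 parameters each. Default reference-level
rates are therefore ~10× inflated (0.3–0.9% per exam depending on
stratum), with `realistic_rates=True` restoring registry magnitudes. The
inflation shifts intercepts only; every structural property under test
(score identities, bias directions, recovery) is rate-invariant.

**What the generator does not emulate**: correlation between menopause and
age (menopause is drawn per race, so young postmenopausal records occur);
covariate–covariate dependence beyond race (e.g. density–BMI correlation
is only induced through race); within-woman correlation across repeated
rounds (covariates other than age are frozen); calendar effects and the
registry's eligibility cascade (records are generated already-eligible).
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generating law, not performance on real
registry data.

Missingness is MCAR per variable by default; setting `age_slope` or
`biennial_shift` makes the masking probability logistic in age and
interval — both always observed, so the mechanism is MAR and correctable
by the chained-equation conditionals.

## Multiple imputation

All maskable covariates are categorical, so every MICE conditional is a
binary/multinomial logistic regression of the variable on all other
covariates, scaled age, interval, and the outcome indicators. Missing
entries initialize from the observed marginal; variables are visited in
ascending missingness order for 10 sweeps (default); each missing value is
redrawn from the fitted conditional class probabilities. Conditional fits
carry a light ridge penalty (C = 10), which also guards against perfect
separation in sparse levels. Draws omit posterior parameter uncertainty
(improper multiple imputation); for the pipeline's purpose — pooled point
predictions, not Rubin-rules inference — this is adequate and is the
reason no coefficient-variance pooling is offered. M defaults to 15.
Pooling of per-imputation predicted risks is the arithmetic mean on the
probability scale. With zero missingness every completion equals the
input, making the imputation stage exactly transparent.

Imputation runs once on the full dataset before cross-validation. This
leaks a small amount of covariate information across folds; with rare
outcomes and covariate-driven conditionals the effect on AUC is
negligible, but a strict per-fold analysis can be run by calling
`fit_mice` on each training fold directly.

## Per-round models and fitting

Each (menopause × interval) stratum gets two logistic fits: advanced
cancer on all exams, competing event on the advanced-free subset (a tree
factorization of the three-state outcome; a multinomial fit is the obvious
alternative and was not implemented). The design uses a raw age
polynomial; internally age enters in decades for conditioning and
coefficients are rescaled back before reporting.

Fits are exact maximum likelihood: a statsmodels Newton solve followed by
in-package Newton refinement until the score inf-norm falls below 1e-7
(typically 1e-11). The refinement matters because the audit's central
identity — in-sample Σ predicted = observed count within every design
level, hence E/O = 1.00 per race group for the race-aware variant — is the
score equation itself and holds only as tightly as the gradient vanishes.

Degenerate levels are profiled out before maximizing: a level with no
exams in the stratum is dropped (coefficient 0); a level whose exams are
all events or all non-events has its MLE at ±∞, represented as ±30
log-odds with its rows excluded so the remaining fit is still an exact MLE
and the identity survives. Residual separation or collinearity falls back
to a ridge-penalized fit (C = 100), logged and flagged `penalized=True`
with SEs reported as NaN — never silent.

## Cumulative risk and standardization

Six-year risk compounds per-round predictions in discrete time,
`risk(K) = Σ q_k Π_{j<k} (1−q_j)(1−c_j)`, with K = 6 annual (age +1
year/round) or K = 3 biennial (+2 years), advanced cancer evaluated before
the competing event within a round (matching the fitting factorization).
Ages advance nominally (+1/+2) rather than by observed mean intervals, and
the menopausal stratum is held at baseline for all rounds — a
simplification; pre→post transitions over six years are not modeled. When
predictions pool over imputations, pooling happens per round before
compounding. Risks are reported as percentages to three decimals;
computation is unrounded.

Standardization weights are reference-cell proportion over empirical
cohort proportion on (age decade × race × family history) cells. The
packaged reference is an independent-margins table (a synthetic stand-in
for census-based weights); `option="cohort"` self-standardizes (all
weights 1). One weight set standardizes annual and biennial screeners to
the same population.

## Evaluation and stratification

Calibration CIs resample women, not exams, preserving clustering of
repeat screens (percentile bootstrap, B = 1000 default; replicates with
zero observed events in a group are dropped and counted, >10% dropped
flags the group). Cross-validation partitions women into k = 5 folds,
stratified by event status so every fold holds events; one AUC is computed
from the pooled out-of-fold predictions (more stable than averaging fold
AUCs under rare outcomes). AUC is the Mann–Whitney statistic with ties
counting one half (computed via scikit-learn; the test suite cross-checks
a brute-force implementation).

Risk categories use weighted percentiles at 5/25/75/95 of the combined
annual + biennial sample, each variant from its own distribution —
thresholds are never shared across variants, so reclassification reflects
rank changes, not scale changes. The weighted-percentile rule is
left-continuous everywhere (thresholds, medians, IQRs): the p-th
percentile is the smallest value whose cumulative normalized weight
reaches p/100, with cumulative weights within 1e-9 counting as reaching it
(guards float cumsum on exact ties). Category boundaries are inclusive
below (a risk exactly at the 95th-percentile cut is intermediate).
Distribution displays are emitted as 5/25/50/75/95 weighted percentiles
per race × cancer-status cell rather than rendered plots.

## Reproducibility and problem sizes

A single master seed fans out to per-stage seeds through a
`numpy.random.SeedSequence` spawn tree; identical config + seed gives a
byte-identical report bundle. The test suite validates the structural
claims on cohorts of 4,000–200,000 exams (with a 10⁶-exam sample for the
discrimination oracle and 10⁶ Monte-Carlo replicates for the compounding
oracle) — sizes at which every targeted property is resolvable well beyond
its tolerance. The acceptance script uses 200,000 exams. Statistical
assertions on stochastic quantities use pre-stated error bands (3 binomial
SEs, 2-SE coverage ≥ 90% across coefficient panels, 3 MC SEs).

## Known limitations

- Synthetic-only: no adapter for real registry extracts; conclusions about
  real-data performance do not follow from these tests.
- The competing-event model is a simplification (no life tables, no
  post-event follow-up); risks beyond six years are out of scope.
- Improper MI understates between-imputation variance; do not use the
  completion spread for formal inference.
- Bootstrap and cross-validation constructions are conventional choices;
  alternative CI constructions (e.g. DeLong for AUC) are not provided.
- Optimal clinical thresholds, screening harms, and preference weighting
  are out of scope.
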