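# Methods

This note records the models, conventions and numerical choices behind
`icuvalid`, and what the synthetic experiments do and do not establish.

## Cohort model and exclusion cascade

The cohort is an admission-level table (see `icuvalid.cohort.COLUMNS`).
Exclusions are applied in a fixed order: (1) records flagged as excluded
from severity-of-illness scoring, (2) readmissions within the same acute
hospital stay, (3) missing hospital mortality, (4) missing age, location
prior to admission or diagnosis code, (5) diagnosis token unmappable under
the supplied mapping table. A record is attributed to the *first* stage
that removes it, which makes the per-stage counts well defined and the
report reconcile exactly (`total_in − Σ removed = total_retained`).
Because each criterion is record-intrinsic, permuting the stages can move
records between stages but never changes who survives; the suite asserts
this on randomised inputs.

Stage 4 removes the *union* of the three missingness criteria, counted
once per record. Within the deterministic test fixture the
missing-location and missing-diagnosis sets overlap by 11 records (16 and
864 members respectively, union 869), which is the only structure
consistent with the published per-field and per-stage counts.
Readmission status is read from an explicit flag rather than re-derived
from identifiers: the linkage rule that produced it is not part of this
package's scope.

## Harmonisation

**Location recoding.** Admissions from an imaging department or a
recovery area used as a temporary critical-care area take their weighting
from the location before that waypoint. When no previous location was
recorded (older dataset versions recorded only one), the most common true
origin is assumed: emergency department for imaging, general ward for
recovery. The recode is idempotent; if the recorded previous location is
itself a transient category the same defaults apply, which is what makes
idempotence hold unconditionally.

**Sedation.** Where sedation was not recorded, an admission with no
lowest Glasgow Coma Score in the first 24 h is assumed sedated. The rule
is driven by presence, not value; a recorded GCS outside 3–15 is an input
error.

**Imputation of physiology extremes.** The lowest systolic pressure is
imputed from {highest SBP, its paired DBP, lowest DBP, its paired SBP},
and the lowest pH from the pH at the lowest PaO₂, each by ordinary least
squares on training rows where both sides were observed. Plain linear
terms are used throughout — no interactions or transforms — and no
coefficient constants are bundled: models are fitted on training data or
supplied as JSON. The source studies announce such equations without
printing them, so shipping invented constants would misrepresent them.
Predictions are clamped to physiological ranges (SBP 0–300 mmHg, pH
6.0–8.0) so a malformed input cannot propagate nonsense into scoring; the
clamp bounds are this package's choice. Degenerate designs (collinear
predictors, too few rows) are errors, not warnings.

**Diagnosis mapping.** Source tokens map to a five-tier hierarchical code
(type, body system, anatomical site, process, condition); `resolution` is
the deepest populated tier and `unmapped` is a value, not an exception, so
the exclusion cascade can count it. Weight lookup walks the code's prefix
chain from deepest to shallowest and takes the first table entry — coding
to the system tier is always sufficient. Mapping tables are JSON (the
five-level nesting is awkward to express unambiguously in flat delimited
text); a bundled demo table covers every tier depth and is explicitly
synthetic.

## Risk-model engine

A model spec is an intercept plus ordered terms — continuous
(`coefficient × transform(field)`), categorical (level → weight map, with
an optional reference level at weight 0) and interaction (continuous field
× per-level weight) — under a fixed logistic link. Log-odds are clamped at
±35 before exponentiation: risks remain strictly inside (0, 1) while being
indistinguishable from 0/1 at double precision. Specs serialise to JSON
and reload to bit-identical predictions.

The engine deliberately consumes *user-supplied* coefficient tables and
precomputed physiology scores. The coefficient sets of the major
published ICU models and their physiology-score weightings are not public;
the bundled demonstration spec is synthetic and labelled as such. For the
legacy score's assembly, only the age-category boundaries (≤44, 45–54,
55–64, 65–74, ≥75) are fixed in code; the point values per category and
the chronic-health points are configuration.

## Statistics

All statistics are computed from first principles; established libraries
are used only for primitives (ranking, distributions, the logistic MLE)
and, in the tests, as independent cross-checks.

- **c index**: midrank formulation, O(n log n), identical to all-pairs
  counting with ties at half. Standard error via DeLong structural
  components: for death i, V₁₀ᵢ is its empirical placement among
  survivors; var(ĉ) = S₁₀/m + S₀₁/n. The 95% CI is the symmetric normal
  interval ĉ ± 1.96·se.
- **DeLong paired test**: variance of the difference from the paired
  covariance of the components; comparing a model with itself, or with any
  strictly monotone transform of itself, gives difference 0 and p = 1.
  When two models score different admission subsets, the comparison is
  computed on the intersection.
- **Hosmer–Lemeshow**: ten equal-sized groups by predicted probability
  (records with identical risk stay together, so heavy ties may produce
  unequal or fewer groups); χ² = Σ (o−e)²/(n·π̄(1−π̄)); **df = number of
  groups**. That is the convention for externally developed models whose
  coefficients were not estimated on the validation data, and it is the
  only df choice consistent with published (χ², p) pairs of this study
  type (e.g. 18.8 → 0.043 requires df 10, not 8).
- **Cox calibration regression**: logistic fit of observed survival on
  predicted survival log-odds. The joint test of (intercept, slope) =
  (0, 1) is a likelihood ratio against the offset model on 2 df, hence
  p = exp(−χ²/2) exactly; published pairs satisfy this identity, while a
  Wald form (also 2 df) would not be distinguishable from print precision
  alone — likelihood ratio was chosen and is documented here.
  Non-convergence and separation raise errors with diagnostics.
- **Accuracy**: Brier = mean (y−p̂)²; Shapiro's R = exp(mean ln(assigned
  probability)). Both are scaled against the constant null model p̄ (the
  cohort death rate): ss_R² = 1 − Brier/Brier_null, entropy_R² = 1 −
  ln R/ln R_null. Probabilities are clamped to [1e−10, 1−1e−10] before
  any logarithm; the clamp keeps everything finite without materially
  moving any statistic.
- **Wilson score interval** in closed form; bounds are snapped to exactly
  0 (k = 0) and 1 (k = n) at the boundary, where the closed form is exact.
- **ROC**: points at every distinct threshold; the trapezoid area equals
  the c index under the tie convention.

## Synthetic cohorts

The generator emulates the published case mix: year weights from the
published per-year admission counts; age truncated-normal 57.5 ± 18.0 on
[16, 100]; 56.1% male; surgical status from the published counts
(normalised — the printed three-way counts sum 27 short of the cohort,
evidently missing/other statuses); physiology score gamma-distributed with
shape and scale solved from mean 19.6 and SD 9.5, rounded to integers in
[0, 100] (the right skew reproduces median < mean). Outcomes are drawn
from a synthetic logistic true model over score, age, urgency, CPR,
diagnostic body system and a score×system interaction; its predictions
are therefore well calibrated by construction. The slope-type
coefficients were chosen, and the intercept solved numerically once, so
that the default cohort reproduces the published mean predicted risk
(≈0.30), risk spread (SD ≈ 0.27) and discrimination (c ≈ 0.845); they are
frozen in `default_model_spec`.

The competitor prediction set is derived from the true one by two
separable distortions on the survival log-odds scale:

1. **linear miscalibration** log-odds′ = c + d·log-odds, with default
   (c, d) = (0.2857, 1.0989) — the inversion of the published legacy-model
   calibration pattern (Cox intercept −0.26, slope 0.91), so Cox
   regression on the distorted set recovers (−c/d, 1/d);
2. **additive Gaussian log-odds noise** (information loss). A purely
   monotone distortion cannot change the c index, so the discrimination
   gap requires noise; `COMPETITOR_NOISE_SD = 1.0` produces a gap of
   roughly 0.04 at the default case mix, matching the published contrast
   in kind and size.

A separate deterministic fixture of 29,626 records reproduces the
published exclusion cascade exactly, including the flagged-admission
sub-reason taxonomy with its outcome summaries (3,529 of 3,599 with a
reported outcome, 731 deaths) and the per-year death counts of the
retained 23,269. Sub-reason outcome denominators smaller than the
sub-reason counts are taken verbatim (outcome is genuinely missing for
the remainder).

**What the generator does not emulate**: unit-level clustering, seasonal
admission patterns, correlated missingness, genuine physiology-to-score
mappings, or dataset-version drift. Passing tests therefore demonstrate
that the *statistical machinery* is correct under the stated case mix,
not that any particular published model is valid on real external data.

## Problem sizes and experiment design

Parameter-recovery experiments use 50 seeded replicates of n = 50,000 —
large enough that Cox calibration CIs are narrow around the truth and the
paired DeLong test has essentially full power at the configured noise
level, small enough to run comfortably on a laptop. The bootstrap
cross-check of the DeLong variance uses 10,000 paired resamples at
n = 200. Oracle-equivalence checks (all-pairs c index) use 100 random
sets of n ≤ 60 where brute force is exact and fast.

## Known limitations

- The exclusion-impact simulation requires category labels on the records
  (`impact_category`); it does not re-derive exclusion eligibility from
  raw fields.
- Cox calibration relies on the statsmodels logistic MLE; near-separated
  inputs error out rather than returning penalised estimates.
- The Hosmer–Lemeshow grouping keeps tied risks together, so with coarse
  risk distributions the test may effectively run on fewer groups (df
  follows the realised group count).
- No recalibration machinery is provided: the engine evaluates supplied
  coefficients, it does not refit them.
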