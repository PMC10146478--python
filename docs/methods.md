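# Methods

This note records the scientific model the package implements, the
numerical choices made where the design was open, what the synthetic-data
generator does and does not emulate, and the known limitations.

## The virtual-controls procedure

The package constructs counterfactual comparison cases for a treated
cohort in three steps.

1. **Scoring.**  Ordered survey responses are mapped linearly onto
   [0, 10], most-protective response = 10 (reversed where the raw order
   runs the other way); the psych score is the arithmetic mean of the
   13-item battery.  A score is *missing*, never zero, when fewer than
   `min_items_required` items are present (default 7 of 13 — a majority
   rule; no published rule exists, so it is configurable).  Internal
   consistency is summarized by Cronbach's alpha,
   α = k/(k−1)·(1 − Σ item variances / total-score variance).

2. **Normative modelling.**  A pooled cross-sectional sample supplies,
   for each age-month in [120, 240], the empirical psych quantile at each
   grid percentile (linear-interpolation quantile; the quantile definition
   is not published, so the most common one is used).  Age-months with
   fewer than 20 records are omitted and covered by the smoothing step.
   Each percentile is then fitted by OLS as a quadratic in age-months.
   Independently fitted quadratics can cross; since matching requires a
   coherent ordering, evaluated values are clamped to [0, 10] and each
   monthly age column is re-sorted so psych is non-decreasing in
   percentile.  The default grid is 0.5–99.0 in steps of 0.5 — 198
   percentiles × 121 ages = 23,958 cells, matching the published cell
   count (the published percentile *range* phrasing is internally
   inconsistent with that count; the count is taken as authoritative and
   the grid is configurable).

3. **Calibration, matching, comparison.**  Per behavior, a logistic model
   with exactly two predictors — Psych and Psych×Age (months), no age main
   effect — is fitted by maximum likelihood (statsmodels) on treatment
   pretests.  A prevalence guard withholds weights when positive cases
   number fewer than `min_positive` (default 20): with near-zero
   prevalence the MLE is unstable, which is why cigarette smoking could
   not be calibrated in the original evaluation.  Each treated case is
   pegged to the grid percentile whose curve value at the pretest age is
   nearest the pretest psych score; ties break to the *lower* percentile
   (lower psych = higher risk, the conservative choice).  Ages below 120
   months are excluded (the normative pool contains no younger
   respondents); ages above 240 are clamped to 240 with a logged warning.
   Scores above the top grid curve clamp to the top percentile (how the
   published algorithm treated them is unstated; clamping is logged).
   The pegged percentile is fixed forever; later-wave psych scores and
   behaviors of the treated student are never consulted, so a virtual
   value exists at every wave the student was surveyed and differential
   attrition is structurally impossible.

Comparisons use the Welch unequal-variance t-test (the t-test flavor is
not published; Welch is the safe default for the mixed 0/1-vs-probability
scales) with Welch–Satterthwaite df, and Cohen's d = (mean_control −
mean_treatment)/pooled SD, so positive d means the counterfactual
estimate exceeds the treated group's reports.  Classroom aggregation is
the unweighted mean over member students; school aggregation defaults to
the mean over all students in the school (student-weighted), with a
mean-of-class-means option.  Subgroup contrasts (boys/girls,
Hispanic/non-Hispanic, White/non-White) use the pooled two-proportion z
statistic with equal n per side (twins inherit demographics, so sides are
equal by construction), treatment prevalence against the mean
virtual-control probability.  Pretest-to-later change is dichotomized
(1 = strict increase) into an analysis-ready table for external
multi-level modelling software; the MLM fits themselves are out of scope.

Degenerate inputs: zero variance on both sides with equal means yields
t = d = 0; with unequal means the contrast is flagged degenerate rather
than given an undefined statistic.  Contrasts with fewer than two units
per side at a given aggregation level are skipped with nothing reported.

## The synthetic-data generator

The generator exists so every stage is testable end to end without any
external download.  It emulates:

- a **normative pool** whose psych scores decline with age at every
  percentile, fastest at the bottom.  The curve family anchors the 25th
  and 50th percentiles at the published sample quadratics exactly, and
  brackets them with invented but non-crossing curves at the 0.5th, 10th,
  75th, 90th and 99.5th percentiles (the published 75th-percentile curve
  is a ceiling-clamped constant and is replaced by a gently declining
  variant in the family so the upper anchors stay ordered).  Coefficients
  interpolate linearly between anchors; a validation pass rejects any
  crossing family.
- a **nested trial cohort**: students in classrooms in schools; pretest
  ages ~Normal(130, 5) months (≈10.8 years), posttest ≈ +2 months,
  follow-up ≈ +10 months; demographic mix 48.5% male, 14.9% Hispanic,
  59.4% White, 17.3% Black; behavior flags drawn Bernoulli from the
  logistic link at each student's realized psych under "true" weights
  (the published alcohol/drunkenness/vaping weights; cigarette uses
  invented weights giving ~0.1% prevalence so the guard trips, as in the
  study).  Default cohort size 77×4×20 ≈ 6,160 pretests, matching the
  combined two-cohort sample.
- **attrition** factored as whole-school dropout × independent student
  dropout (0.67×0.50 at posttest, 0.60×0.405 at follow-up), reproducing
  the study's overall 33.5%/24.3% retention while reflecting that schools,
  not students, drove the loss.  The factor split itself is not published;
  it is a one-time modelling choice.  Posttest and follow-up school
  dropout are drawn independently (follow-up occurred the next school
  year, so a school missing posttest may return).
- **item responses** as essentially parallel items: item = psych +
  Gaussian noise, with the per-item noise variance in closed form so the
  expected Cronbach's alpha hits a target (default .681) given the
  between-student psych variance, then clamped to [0, 10].
- a **program effect** parameterized as a psych lift δ ≥ 0 after pretest
  plus an additive shift on the behavior log-odds after pretest
  (negative = protective).  Neither quantity is published; both default
  to zero.  The additive log-odds parameterization replaces a
  "multiplier" phrasing whose sign is ambiguous when log-odds are
  negative.
- two psych-noise presets: `study_like` (σ = 0.9, mirroring the weak
  pretest psych–behavior coupling observed in the live evaluation) and
  `norms_like` (σ = 0.3, the tighter coupling of the pooled norms).
  Latent percentiles are uniform by default, with a `topheavy` preset
  (13% near the ceiling, ~70% below the 60th percentile) mirroring the
  assigned-percentile distribution the evaluation reported.

### What the generator does *not* capture

Real item responses are skewed and bounded, not Gaussian around a latent
score: near the scale ceiling the parallel-items emulation clips heavily,
which biases observed psych scores *downward* relative to the latent
score (by several tenths at α = .681 and mean psych ≈ 8.7).  The real
procedure is insensitive to such a location shift because its weights are
calibrated on the very same observed scores — but any analysis mixing
generator-scale ("true") weights with item-scored psych inherits the
shift.  Pandemic timing, officer characteristics, fidelity ratings and
cohort-year effects are not modelled.  Passing tests therefore show the
pipeline's internal consistency and statistical calibration under a
faithful structural emulation, not agreement with the live study's
empirical tables, which would require the real data.

## Calibration of the null test, and problem sizes used

The type-I-error check simulates zero-effect cohorts of 1,000 students
(10 schools × 4 × 25, attrition off so every comparison uses the stated
n), pegs cases on the generator's realized psych scores, computes virtual
probabilities from the generating weights, and Welch-tests alcohol at
posttest.  This harness isolates the matching + comparison machinery.
Two effects make it mildly conservative (true size ≈ 4% by a
3,000-replicate estimate rather than 5%): the two-sample test ignores the
positive matched-pair correlation between conditions, and the pegging
floor (the lowest grid curve) clamps out-of-model noise in the risk-heavy
low-psych tail.  The test uses 600 replications so the Monte-Carlo
standard error (~0.8%) is small against the acceptance band.

Two method-inherent instabilities are deliberately *excluded* from that
harness and documented instead: (a) with per-trial calibrated weights,
the Psych×Age coefficient is nearly unidentified from pretest-only ages
(SD ≈ 5 months), and extrapolating it even two months inflates the
false-positive rate severalfold at n = 1,000 — the published caution that
near-zero prevalence makes the weights unreliable understates how much
the age-interaction term suffers; (b) the item-emulation ceiling bias
described above.  Both are real phenomena a user should expect at small
samples, not implementation defects.

Other simulation sizes: parameter recovery uses 50,000 direct draws from
the logistic model; matching-oracle equivalence uses 1,000 random small
tables including engineered near-ties; the attrition invariant uses a
960-student cohort at the study's default (≈66.5%) posttest attrition;
norm-curve recovery concentrates 150,000 pool records on an 11-month age
band so per-age sample-median noise is well under the 0.1 tolerance.

## Numerical choices

- Quantiles: linear interpolation between order statistics.
- Quadratic fits: `numpy.polyfit` (OLS on raw psych values; whether the
  published fits used any transformation is unstated).
- Curve serialization writes 17 significant digits and reads with
  round-trip float parsing, so save → load → evaluate is bit-compatible.
- Matching tie-break: `argmin` over an ascending-percentile column
  returns the first minimizer, i.e. the lower percentile, exactly.
- Logistic fits: statsmodels `Logit`, Newton default, convergence flag
  and standard errors propagated; non-convergence or separation yields a
  guarded report, never silent weights.
- Probabilities are computed with `scipy.special.expit` and are strictly
  inside (0, 1).

## Known limitations

- Virtual controls inherit the normative table's population; if the
  treated population differs systematically from the pooled norms, pegged
  trajectories misstate the counterfactual.  The package cannot detect
  this.
- The mixed-scale comparison (0/1 reports vs. model probabilities)
  understates control-side variance at the student level; aggregate
  levels are less affected.  This follows the published design and is
  reported as such.
- Printed t/p pairs in the published outcome tables are partly
  inconsistent and some published subgroup prevalences are negative
  (suggesting they are changes, not prevalences); the package reports
  plain prevalences and makes no attempt to reproduce those entries.
- The published worked example's drunkenness and vaping probabilities are
  not reproducible from the rounded published weights (their printed
  Psych×Age entries of 0.000 imply ~0.25% and ~0.41% rather than the
  printed 0.02%/0.04%); only the alcohol values are used as exact checks.
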