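# Methods

## Problem setting

The package estimates an individual's risk of a future disease diagnosis
from the outpatient diagnosis codes recorded *before* that diagnosis ever
appears. The working hypothesis is that early symptoms and comorbid
conditions leave a low-dimensional trace in the diagnosis stream: a small
number of latent "disease themes" explain which codes a patient
accumulates, and some of those themes are enriched in patients who later
develop the target disease.

## Preprocessing model

ICD-9-CM codes are normalized to a canonical five-character form: the
integer part is left-padded with zeros (three digits; two after a leading
`V`; three after a leading `E`) and the fractional part is right-padded
(two digits; one for `E` codes), e.g. `714.0 → 71400`, `7.1 → 00710`,
`V4.5 → V0450`. Normalization is idempotent, and undotted inputs are split
positionally at the integer-part width.

Noise removal is total (it never fails) and attributes each removed record
to exactly one of three rules, checked in order: (1) *incorrect format* —
unnormalizable codes, or patient identifiers that are not alphanumeric of
the configured length (default 10); (2) *missing/out-of-window* —
unparseable visit dates or dates outside the observation window (default
2000-01-01 to 2008-12-31); (3) *garbled* — fields empty after stripping or
containing non-printable characters. Empty or non-printable fields fall
through to rule 3 rather than being counted as format errors. Real claims
databases do not document their noise precisely, so all rule parameters
are configuration, not constants.

## Cohort definitions

A **case** needs at least `min_dx` target-code diagnoses (default 2 —
"diagnosed more than twice" is read inclusively, matching common claims
practice; the threshold is configurable because the literal reading would
be ≥ 3) *and* membership in an external registry. The case history is all
non-target records strictly before the first target diagnosis, which
becomes the censor date; this guarantees no post-diagnosis leakage. A
**control** has ≥ 1 record in the window and zero target-code diagnoses.
Patients with target-code evidence below the case threshold are excluded
from both arms, so neither arm carries a contaminated label. Descriptive
summaries use Student's two-sample t for continuous per-patient measures
and Pearson's chi-squared (no continuity correction) for the sex
proportion.

## Factorization

The binary patient–disease matrix is factorized by minimizing the squared
Frobenius residual with the standard alternating multiplicative updates
(see the `factorization` module docstring for the update equations). Key
numerical choices:

- **Stabilizer** ε = 1e−12 added to the update denominators only; the
  monotone-descent guarantee of these updates then holds up to ~1e−9
  floating-point slack, which is what the tests assert.
- **Initialization**: Uniform(0, 1) entries from a seeded
  `numpy.random.default_rng`; restart *i* of an `n_restarts` fit uses
  `seed + i`, and the restart with the lowest final objective wins.
  Default is a single run.
- **Stopping**: relative objective change below `tol` (default 1e−4) or
  `max_iter` sweeps (default 500); the objective is recorded every sweep,
  trace index 0 being the initial value. `tol=0` disables early stopping.
- **Scale convention**: after fitting, `DR` columns are normalized to unit
  Euclidean norm with the scale moved into `PR`. The reconstruction and
  objective are unchanged; the point is that classifier features (rows of
  `PR`) live on a comparable scale across cross-validation refits.
- **Fold-in**: one patient's loading is obtained by the same
  multiplicative update with `DR` fixed, an all-ones start, and an
  h-change stopping rule (default tol 1e−10, 500 iterations). The
  single-row problem is convex, so this converges to the nonnegative
  least-squares projection; an all-zero row is a fixed point and returns
  the all-zero loading. Sparse and dense inputs give value-equivalent
  results; the sparse objective uses the expanded trace identity so the
  dense residual is never materialized.

The default evaluation mode is **inductive**: the factorization is refit
on each training split and test rows are folded in, so test patients never
influence the factor space. A **transductive** mode (factorize once before
splitting) reproduces the historical protocol at the cost of feature-level
leakage; it is exposed but not the default.

## Risk classifier and parameter selection

The classifier is a soft-margin RBF-kernel SVM on the patient loadings,
with defaults C = 2 and γ = 2⁻⁵ = 0.03125. A grid-search helper re-derives
them on new data by inner stratified CV over the customary powers-of-two
grids (C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, exponent step 2), breaking ties toward
the smaller C then the smaller γ. Decision scores (signed distances) are
returned alongside labels so downstream users can re-threshold.

The factor count R is selected by sweeping candidates (historically 100 to
900 in steps of 100 on a balanced sample) and applying a lexicographic
rule: discard ranks whose sensitivity–specificity gap is ≥ 5% (the gap cap
is configurable), then choose the highest mean accuracy, then the lowest
accuracy SD, then the smallest R; if no rank satisfies the gap constraint
the minimal-gap rank is returned with a warning.

## Evaluation protocol

Stratified k-fold assignment is per-class shuffled round-robin from a
seeded generator, so per-class fold counts differ by at most one and the
assignment is reproducible. Metrics are macro-averaged over folds (a
pooled-confusion variant is available behind a flag), and the spread is
the population SD (divide by N). A zero denominator yields NaN plus a
warning, never a silent zero. The grouped-control design evaluates one
case set against many disjoint, seeded control groups (defaults 50 groups
of 500) and reports per-group results with a grand mean/SD.

## Synthetic cohort generator

The generator emulates the structure the model assumes, which is precisely
what makes it useful for validation and what limits it as evidence about
real data:

- Each of k themes (default 5) activates ≈ `theme_code_sparsity · M` codes
  (default 5% of 400) with Uniform(0.5, 1.5) loadings.
- Patient theme weights are Gamma(shape 4, scale 0.15); mean 0.6 yields a
  realistic ~10% matrix density, and the log-scale spread (≈ 0.53) keeps a
  boost of 3 on the designated risk themes (default 2 of 5) an effect a
  well-specified pipeline can recover. Case rows get their risk-theme
  weights multiplied by `case_theme_boost`; boost 1 gives an exchangeable
  null cohort.
- Binarization is `P(v=1) = 1 − exp(−(λ + b))` with `λ = PR·DRᵀ` and a
  background rate b (default 0.02) of incidental, theme-free diagnoses so
  every code can occur. Patients with an empty profile receive one code
  drawn from their own intensity profile — cohort members have at least
  one diagnosis by definition.
- Profiles are expanded into dated visit records (Poisson visit counts,
  default 6/year over the 9-year window, dates uniform — temporal order
  carries no signal because the matrix is time-agnostic). Cases receive
  two target-code records dated after all other records, so censoring at
  the first reproduces the planted profile exactly. The registry lists all
  cases plus an optional false-entry rate. Malformed records (bad
  identifier, garbled code, out-of-window date) are appended at
  `noise_rate` (default 2%).

Defaults are a balanced 500/500 cohort, mirroring the balanced design used
for rank selection; a rare-disease regime (e.g. 10 cases / 9,990 controls
for 0.1% prevalence) is one configuration away.

What passing on this generator does **not** show: robustness to real EMR
phenomena the generator omits — code-frequency power laws, comorbidity
network structure, temporal drift in coding practice, informative visit
timing, miscoding correlated with outcome, and the extreme 0.1% prevalence
of the motivating cohort (the balanced default sidesteps the
class-imbalance problem, as the historical protocol did by sampling).

## Problem sizes

The test suite and the acceptance script run the full pipeline at
1000 patients × 400 codes with R = 5 and 10-fold CV (about 3 s per CV on
one CPU), and verify the factorization guarantees on matrices up to
50 × 40 over a hundred random problems. These sizes were chosen so the
whole validation cycle stays interactive; the algorithms themselves are
dense-BLAS bound and scale to the tens of thousands of patients and
thousands of codes of a real claims extract.

## Known limitations

- The multiplicative updates converge to a stationary point, not a global
  optimum; restarts mitigate but do not remove initialization dependence.
- Fold-in treats `DR` as fixed, so a test patient whose profile lies far
  outside the training span is poorly represented.
- The SVM is used with fixed (C, γ) unless the grid search is invoked;
  no probability calibration is provided, only decision scores.
- Sub-threshold target-code patients are excluded entirely; incidence
  density sampling and covariate matching are out of scope.
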