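# Methods

## Model

One-year weight transitions are modelled piecewise-linearly.  A binary
gating tree on baseline BMI, age and sex routes each person-year to one of
a small number of leaves; each leaf is a sparse linear formula in the
continuous state (baseline weight, prior-year weight difference, height,
age, a male indicator) and in lifestyle indicators.  Numeric gates
partition the real line exactly with the boundary on the high side
(`x ≥ threshold`); the packaged published model additionally uses an
`age ≤ 24` gate, the equivalent `age ≥ 25` form on integer ages.

**Feature encoding.**  Every questionnaire answer enters as an indicator
that fires iff the answer equals the level named in the feature key.
Baseline-interview indicators use the year-*t* answers; predictive-year
indicators use the year-*t+1* answers and — except for the
wish-for-health-instruction item and the numeric drinking score — are
gated by the three-level intention-to-improve item: the level-ℓ variant
fires only when the person's intention level is ℓ, so at most one of the
three level variants is ever active.  The three-level eating-speed item
(quicker / normal / slower) contributes separate indicators per level; the
predictive-year "not quicker" variant is encoded as the *slower* level,
since "normal" has its own indicators.  Drinking enters once per interview
as a numeric 0–10 frequency/quantity score (the scale is a modelling
choice; the published coefficients on it are ±0.03 or smaller, so the
scale barely matters).  The full vocabulary is 52 features; laboratory
values (blood pressure, lipids, HbA1c, …) can be appended as candidate
predictors and act as decoys for the selection machinery — they carry no
coefficient in the generative truth.

**Chained forecasting.**  A 3-year forecast iterates the one-year model:
the year-*k* prediction becomes the next step's baseline weight, the
weight difference becomes (predicted − previous), age advances one year
per step (a `frozen-age` toggle exists), and by default the gate is
re-evaluated each year with the updated BMI (`reassign_leaf=False` keeps
the baseline leaf; both modes are tested).  Scenario forecasts hold the
predictive-year questionnaire fixed over the horizon; from the second step
on it also serves as the baseline interview, reflecting answers that
continue unchanged.  Leaf evaluation uses a fixed-order reduction
(`einsum`), so forecasts are bitwise identical whether computed per person
or in batch — the generator and the predictor share this code path.

## Synthetic cohorts

The generator emulates the checkup population the analysis assumes, not
any real individual-level data:

* sex: 66% male; height/weight at baseline from sex-specific normals
  (male 170.8 ± 6.2 cm, 68.3 ± 11.1 kg; female 157.8 ± 5.7 cm,
  54.4 ± 9.6 kg), independently drawn; age from N(48, 12²) truncated to
  19–91.  Independence of height and weight widens the implied BMI spread
  (SD ≈ 4.2 vs ≈ 3.4 in the target population) — a known simplification.
* the weight one year before baseline differs from baseline by
  N(0, 2.0²) kg (assumption; nothing in the target tables constrains it).
* follow-up weights iterate the ground-truth model (default: the packaged
  published model) with additive N(0, σ²) noise fed forward;
  σ defaults to 1.9 kg, calibrated so that one-year forecast error is on
  the scale of the published validation RMSE (≈1.9 kg) — a calibration,
  not an estimate of true within-person variability.
* questionnaire answers: year-0 marginals are plausible assumed values
  (e.g. 25% heavy smokers, 70% sleeping well, eating speed
  0.30/0.55/0.15, intention levels 0.30/0.40/0.30, drinking score
  Binomial(10, 0.3)); each answer persists year-to-year and changes with
  probability 0.1 (multi-level items move uniformly to another level).
* labs are independent sex-specific normals per year (decoy predictors
  only; no correlation structure).
* missingness is person-level MCAR at rate 12,021/67,021 by default: a
  flagged person loses the weight of one random year, which removes the
  person under complete-case filtering.  Only a count is available for
  the real exclusions, so the mechanism is an assumption.

Because the generator uses the predictor's own chaining, σ → 0 with frozen
questionnaires makes generated trajectories equal model forecasts exactly;
tests exploit this as a consistency oracle.  Passing recovery tests on
these cohorts shows the learner can invert this generative process; it
cannot certify behaviour on real checkup data, whose noise is
heteroscedastic, whose lifestyle answers are correlated with weight, and
whose missingness need not be MCAR.

## Learner

A surrogate for heterogeneous mixture learning with a factorized-Bayesian
criterion, whose internals are proprietary.  What is reproduced is the
behavioural contract — the number of partitions and the per-leaf variable
selection are chosen automatically by one penalized criterion:

* **criterion**: Gaussian profile log-likelihood minus
  (k + 1)·log(n_local)/2, with k the selected regression parameters
  (intercept included) and n_local the component's own sample size — a
  component-local BIC.
* **leaf fits**: forward-selection OLS; features enter while the criterion
  improves; unselected features are exact zeros.  Implemented on Gram
  matrices with order-recursive Cholesky updates; collinear candidates
  (pivot below 1e-9 relative) are skipped.
* **splits**: at each node, every gate feature (BMI, age, sex by default)
  is scanned over a 64-quantile threshold grid; the gain of a candidate is
  the children's summed penalized likelihood minus the parent's.  The
  max-gain candidate is accepted iff the gain is positive, depth < 3 and
  both children have ≥ 200 rows (min_leaf_n, which also bounds the leaf
  design).  Ties break on gate order, then lower threshold.  The threshold
  scan reuses prefix sums of per-segment Gram matrices, so one fit on
  60,000 transitions takes a few seconds.
* **training target**: next-year weight, pooling the three observed
  transitions of each person into one shared one-year model (a per-year
  variant would be a trivial extension); multi-year prediction is always
  by chaining, never a direct multi-year regression.

A brute-force oracle (plain lstsq forward selection, exhaustive candidate
enumeration) re-derives the greedy step independently on small instances
and is asserted equal in tests.

**Split-order identifiability.**  Nested gates on the same feature define
the same partition — hence literally the same piecewise-linear function —
in either order, so the learner's split *order* is not a recoverable
parameter.  Empirically the greedy search takes the low BMI cut
(≈ 23.44) first, because it isolates half the data as a pure region,
whereas the published presentation places the high cut (29.93) at the
root.  Recovery diagnostics therefore compare *gate boundaries*, pairing
fitted cuts to reference cuts per feature by nearest value
(one-to-one assignment), and match leaves to reference leaves by region
overlap on a reference sample of (BMI, age, sex) triples; the fitted
tree's positional root is reported alongside for transparency.

## Evaluation

* **RMSE** of chained forecasts on held-out persons, pooled over horizons
  1–3 with a per-horizon breakdown (which pooling the original analysis
  used is not stated; both are reported).
* **baseline**: a single dense OLS model on the identical encoding
  (collinear columns dropped with a warning — the exercise yes/no ×
  intention indicators sum to the constant column), evaluated with the
  identical chained procedure.  On mixture-truth data the mixture's
  training RMSE can never exceed the baseline's (model-class containment);
  tests assert this.
* **model comparison**: unpaired Student t test on per-person mean squared
  errors, matching the stated test family; a paired variant is available
  and is statistically preferable when both models score the same persons.
* **recovery report**: leaf count, matched gate boundaries, per-leaf
  coefficient errors, region agreement.

## Problem sizes, defaults, and observed behaviour

Recovery studies use 10 seeds × 20,000 persons (60,000 transitions) at
σ = 1.0 kg; filtering fidelity uses one cohort of 67,021 persons at the
empirical missingness rate; the end-to-end evaluation driver uses 24,000
generated persons with a 15,000/3,000 split.  These sizes make each stage
take seconds to a few minutes while leaving Monte-Carlo error far inside
the stated tolerances.

With these settings the learner recovers five leaves in 10/10 seeds,
the BMI boundaries to within ~0.1 kg/m² (grid resolution near the cuts),
and the leading coefficients to ~0.01.  The age gate (a ~300-row region)
is the hardest structure: in roughly half the seeds the fifth split spends
its budget elsewhere, so age-cut medians are computed over the seeds that
recover it.  Known limitations: no height–weight correlation, independent
labs, MCAR-only missingness, assumed questionnaire dynamics, and a greedy
search that cannot represent the global criterion of the original
algorithm — only its selection behaviour.
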