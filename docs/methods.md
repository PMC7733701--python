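# Methods

This note records the modelling assumptions, default parameters and design
choices behind `t2demu`, in the spirit of a model-description appendix.

## 1. Cohort design

The cohort is the full factorial product of the nine categorical factors
(sex × age × weight class × height class × activity × diet levels). The
physical-activity factor collapses the sedentary cell: duration and
intensity exist only when the weekly session count is positive, so it
contributes 1 + 3·3·2 = 19 cells and the design has
2·5·3·3·19·27 = 46,170 subjects, partitioning into 90 anthropometric ×
27 diet × 19 activity cells.

**Anthropometric decoding.** Only one concrete anchor is fixed by the
design convention: a tall underweight male is 1.91 m and 65.66 kg. The
package generalises it with two editable fixture tables:

- heights (m): male {short 1.65, average 1.78, tall 1.91} (even 0.13 m
  spacing anchored at the tall value), female {short 1.53, average 1.635,
  tall 1.74};
- class target BMI (kg/m²): underweight 18.0, normal 23.0, overweight 28.0.

Weight is target-BMI × height², **truncated** (not rounded) to two
decimals — the only rule that maps 18.0 × 1.91² = 65.6658 to 65.66.
Truncation means realised BMI0 sits up to 0.01/height² below the class
target; this tiny jitter is irrelevant downstream.

**String codec.** Subject strings are parsed tolerantly: the weight and
height tokens are accepted in either order and "obese" is accepted as an
alias of "overweight" (both variants occur in practice). The canonical
emitted form is `sex age weight_class height_class N [D/I] C/P/F`.

## 2. Energy model

- REE: Mifflin–St Jeor, `10·w + 6.25·h_cm − 5·age + (+5 male | −161
  female)` kcal/day.
- AEE: a VO2-based fixture. Relative VO2max (mL/kg/min) is 50 (male) / 42
  (female) at age 20, declining 0.30 per year, floored at 20. Oxygen
  uptake at a session is VO2max_rel · (intensity/100) · weight/1000 L/min,
  costed at 5 kcal per litre of O2, times duration, averaged over the week.
  This is an explicit stand-in for a full exercise-physiology model; its
  absolute calibration (~80 kcal/day for one hour weekly at 60% VO2max for
  a 66 kg man) is realistic but not validated against any dataset.
- TEF: defined as 10% of intake. At caloric balance intake = TDEE, so the
  circular definition TDEE = REE + AEE + 0.1·TDEE is resolved exactly as
  TDEE = (REE + AEE)/0.9.
- Meals: 25/45/30% of TDEE; each meal 50/20/30% carbohydrate/protein/fat
  calories; Atwater general factors 4/4/9 kcal/g; level multipliers
  low 0.8, med 1.0, high 1.5 applied to grams uniformly across meals.
  The all-med diet is therefore calorically balanced by construction, and
  the energy imbalance of any diet reduces to
  E = 0.5(c−1) + 0.2(p−1) + 0.3(f−1) in the level multipliers.

## 3. Synthetic simulator

The true simulator is out of scope; the generator is an explicit response
surface whose only obligations are the statistical features the analysis
pipeline must be able to detect:

1. **Nonlinearity in BMI0** — hinge terms max(0, BMI0−25)^1.5 on glucose
   and max(0, BMI0−22) on TNF-α.
2. **A graded effect hierarchy** — BMI0 and carbohydrate level dominate BMI
   and glucose; age dominates TNF-α; protein, fat and sex have smaller but
   real effects; the three physical-activity variables act only through the
   weekly activity dose N·D·(I/100)/60 with deliberately small
   coefficients. Each non-activity effect variance is sized at least ~4×
   any single activity-variable effect variance so that importance rankings
   are stable at the default sample size.
3. **Switch-like risk escalation** — +25 mg/dL on glucose in the
   (BMI0 > 25) ∧ (high-carb) ∧ (age ≥ 48) cell and +0.9 TNF units in the
   (BMI0 > 25) ∧ (age ≥ 48) cell. These threshold interactions emulate the
   discontinuous metabolic/inflammatory transitions of mechanistic
   simulators. They are also what keeps the emulation problem honest:
   every predictor takes at most five distinct values, so any *smooth*
   surface on this lattice is exactly a low-order polynomial and would be
   solved to the noise floor by the degree-4 polynomial surrogate. The
   escalation terms have lattice-polynomial degree > 4 (the age indicator
   alone needs a quartic), so the polynomial family is structurally biased
   while axis-aligned trees capture them naturally — reproducing the
   qualitative gap between polynomial and forest surrogates that motivates
   the method.
4. **Correlated residuals** — ε ~ N₃(0, Σ) with default standard
   deviations (0.3 kg/m², 4 mg/dL, 0.3 units) and pairwise correlation
   0.3. Σ is validated symmetric PSD; noise is drawn through an
   eigendecomposition transform, so Σ = 0 yields an exactly deterministic
   generator.

Glucose (85 mg/dL) and TNF (2 units) baselines are plausible placeholders,
not calibrated values. The generator emulates the *statistical structure*
of simulator output — effect hierarchy, nonlinearity, thresholds,
correlated noise — but none of its mechanistic dynamics (no trajectories,
no immune-system state, no within-subject variability over time). Passing
tests therefore demonstrate that the pipeline recovers planted structure of
this kind, not that any particular clinical conclusion transfers to real
data.

All coefficients are configurable (`ResponseSurfaceParams`, JSON-
serialisable); a single integer seed drives one RNG stream that draws
residuals in design order.

## 4. Surrogate models

- **Predictor encoding:** the 9-vector (BMI0, age, sex∈{0,1}, three level
  multipliers, N_PA, D_PA, I_PA), with activity fields 0 for sedentary
  subjects so the vector is always fully numeric.
- **Polynomial family:** all monomials of total degree ≤ d (d = 1..4),
  including interactions, on z-scored features; ordinary least squares per
  output via SVD (`lstsq`). Because the lattice features have few levels,
  high pure powers are collinear (e.g. sex² = sex); the basis is then rank
  deficient by construction, a warning is emitted and the least-norm
  solution is used. In-sample MSE remains monotone nonincreasing in d.
- **Pooled standardized MSE:** each output is z-scored by its *training*
  mean/sd (population convention, ddof = 0) and the squared errors are
  pooled over all 3·n entries. One scalar per model, comparable across
  outputs and models; the train-mean predictor scores exactly 1 in sample.
  Pooling (rather than averaging per-output MSEs computed on other scales)
  is the convention that makes a unit-variance baseline interpretable.

## 5. Random forest

From-scratch multivariate CART: splits minimise the summed within-child
SSE over the (jointly z-scored) outputs, thresholds are midpoints between
consecutive distinct sorted values, ties break to the lowest feature index
then the smallest threshold. Pure nodes and nodes with no valid split
become leaves; zero-gain splits of impure nodes are allowed (standard CART
behaviour — required, e.g., to fit XOR structure at depth 2). One forest
predicts all three outputs jointly (a multivariate forest), each tree on
its own bootstrap resample with per-node feature subsampling.

Defaults: 100 trees, mtry = 3 (≈ p/3), min_leaf = 5, unlimited depth,
bootstrap on. All randomness flows through one `numpy` Generator seeded by
a single integer, so forests are reproducible bit for bit. Trees
serialise to nested JSON (split variable, threshold, children, leaf mean,
counts) so external tools can traverse the structure.

## 6. Importance analyses

- **Noising-up importance:** within-column permutation of the predictor on
  the evaluation set; importance = mean over replicates of
  MSE(permuted) − MSE(original), per output and pooled. Permutation is the
  default noise scheme; a variable never used by any tree has importance
  exactly 0. Defaults: 5 replicates (singles), 3 (pairs), evaluated on the
  test set with the shared training standardization.
- **Pairwise co-influence:** both columns permuted jointly with
  independent permutations, same differencing.
- **Minimal depth / maximal subtrees:** per tree, D_i is the depth of the
  shallowest split on i (root = 0); maximal i-subtrees are i-splitting
  nodes with no i-splitting ancestor; D_j^i is the minimal depth of a
  j-split measured from the root of each maximal i-subtree, minimised over
  subtrees. Each tree's entries are normalised by (tree height + 1) —
  mapping absent variables to exactly 1 — and the 9×9 matrix is averaged
  with equal weight per tree. The normalisation constant and the
  absent-variable sentinel are package conventions; both are documented
  here because other reasonable choices (e.g. average tree depth) exist.

## 7. Evaluation pipeline

The train/test split is a uniformly random, seeded partition with
round(2m/3) training rows (30,780/15,390 on the full design); no
stratification is applied. The Pearson correlation matrix uses the sample
(ddof = 1) formula and reports NaN with a warning for zero-variance
columns. Reports export as six CSV files plus a JSON metadata record;
reruns with identical config and seed are byte-identical (no timestamps in
outputs). Plots are optional and never part of the canonical outputs.

**Desk-scale defaults.** The default study runs on a seeded 5,000-subject
subsample of the design with 100 trees — the scale at which the full
five-model comparison plus all importance analyses completes in about two
minutes on one CPU while every qualitative conclusion (forest best
out-of-sample with MSE_out/MSE_in ≈ 1.5, BMI0 top for BMI and glucose,
age top for TNF-α, activity variables last everywhere) is stable. The full
46,170-row design is supported through `StudyConfig(n_subjects=None)`.

The master seed derives five sub-stream seeds (subsample, residual noise,
split, forest, importance) via one `default_rng(seed).integers` call, so
the entire chain is reproducible end to end from a single integer.

## 8. Known limitations

- The response surface is a fixture: its coefficients encode a plausible
  effect hierarchy, not fitted physiology; absolute outcome values should
  not be interpreted clinically.
- The AEE/VO2max equations are stand-ins with realistic magnitudes only.
- Anthropometric decoding is a 3×3 class lookup, not a population model;
  continuous age/height/weight sampling is out of scope.
- The forest is single-threaded and optimised for clarity and testability;
  it handles the default scale comfortably but is not an HPC
  implementation.
- Pairwise permutation importance inherits the known bias of permutation
  schemes under correlated predictors; the factorial design keeps the
  predictors orthogonal, which is exactly why the scheme is adequate here.
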