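# Methods

`ertmap` implements a region-ranking analysis for studies that predict
cognitive scores (MMSE, CDRSB, ADAS) from region-level neuroimaging
biomarkers in cohorts spanning healthy controls (HC), mild cognitive
impairment (MCI), and Alzheimer's disease (AD).  This note documents the
model, the statistics, the synthetic-data generator, and the numerical and
design choices that were genuinely open.

## Regression trees with surrogate splits

Trees are grown by greedy binary recursive partitioning of a subjects x
regions feature matrix against one cognitive score.

**Node risk.** For node *t* holding *n_t* of the *n* training samples, risk
is the node's mean squared error about its own mean weighted by the node
probability *n_t / n*, i.e. `R(t) = (n_t/n) * MSE(t) = SSE(t)/n`.  Split
quality is the risk change `R(parent) − R(left) − R(right)`, which is
non-negative for every binary partition.

**Split search.** At each node an `mtry`-subset of features is drawn without
replacement (`mtry = max(1, round(mtry_fraction * p))` in ensembles;
`mtry_fraction = 1` gives pure bagging, the default 1/3 gives random-forest
behaviour).  Candidate thresholds are midpoints between adjacent distinct
sorted values; children must hold at least `min_leaf` samples (default 5,
the conventional default for bagged regression trees).  Growth stops when no
candidate split has positive risk reduction; there is no depth limit and no
pruning.

**Determinism.** Equal-quality splits break toward the lowest feature index,
then the lowest threshold.  Because summation order makes mathematically
equal reductions differ at the last ulp, candidates within `1e-12 * SSE(t)`
of the incumbent count as ties.  A consequence worth knowing: with the
deterministic tie-break, column permutation equivariance of the fitted tree
holds only where no two features achieve exactly equal reductions (ties are
resolved by index, which permutation reorders).

**Surrogate splits.** After a primary split is chosen, every other feature
is scanned for the threshold that best mimics the primary left/right
partition of the node's samples (routing is always value < threshold goes
left; a sign-flipped mimic is therefore not usable as a surrogate).  With
`p_L`, `p_R` the primary split's left/right sample fractions and `p_agree`
the fraction routed identically, the predictive measure of association is

    lambda = (min(p_L, p_R) − (1 − p_agree)) / min(p_L, p_R),

the standard definition: lambda > 0 means the surrogate beats the
majority-routing baseline.  Surrogates with lambda > 0 are kept, ordered by
descending lambda, and truncated to `max_surrogates` (default 10, a
bounded-cost choice that in practice captures nearly all association mass).

**Predictor importance.** Importance of feature *f* is the sum of risk
reductions of every split on *f* — primary and surrogate — over all branch
nodes, divided by the number of branch nodes.  A surrogate's risk reduction
is the reduction *its own* partition achieves on the node's response, not
the primary's; the alternative (weighting by lambda, or crediting the
primary's reduction) is equally defensible but reads less naturally as "the
change in node risk from splits on each feature".  This is the main fidelity
risk relative to other tree implementations and is isolated behind
`predictor_importance` / `find_surrogates`.

## Ensembles

Ensembles fit `n_learners` trees (default 50), each on an independent
bootstrap resample of the training rows, with per-node feature subsampling
as above.  Predictions and importances are unweighted means over trees.
Out-of-bag machinery is deliberately omitted: evaluation uses the explicit
repeated train/test scheme below.

## Repeated train/test resampling

Each iteration draws a uniformly random partition with train size
`round(0.9 n)` (round half up), fits an ensemble on the training part, and
records the held-out MSE, the Pearson correlation between predicted and
actual scores, and the ensemble importance vector.  Splits are not
stratified by diagnosis by default (a `stratify` flag exists).  Correlations
from test sets smaller than two points, or with zero variance on either
side, are recorded as undefined and excluded from correlation summaries;
their MSEs are kept.  All randomness is a deterministic function of a base
seed and the iteration index.

Note that leaf-mean predictors cannot drive the held-out MSE of a continuous
noise-free trend to zero: piecewise-constant interpolation floors the error
near 1e-3 of the target variance, which is what the learnable-signal tests
assert.

## Normalized importance, threshold, consensus

For one (group, biomarker, score) cell, the importance matrix over
iterations is reduced to the **NI profile**: column means, square root,
divided by the cross-region mean of the square roots.  NI is dimensionless
with mean exactly 1 over the panel's regions, making profiles comparable
across biomarkers with different scales and region counts.

The significance threshold comes from a permutation null: the score vector
is shuffled, one train/test iteration is run, and an NI profile is computed
from that single run; repeating this (500 times at full scale) and pooling
all permuted NI values over regions and runs gives one threshold per cell,

    threshold = pooled mean + 2 * pooled SD,

with sample SD (ddof = 1; at hundreds of permutations the population-SD
variant is indistinguishable, and a config flag exposes per-region
thresholds for sensitivity analyses).  Regions are significant when NI
*strictly* exceeds the threshold; ranking is by descending NI with ties
broken by region index.  Two deliberate readings of ambiguous protocol
wording are baked in here: the NI normalizer is collapsed to `s / mean(s)`
(any intermediate rescaling cancels, and only the mean-one property is
observable), and permuted NI is computed per shuffled run rather than from
averaged permuted importances (pooling single-run NI values gives the wider,
more conservative null; the run-averaged variant would shrink the spread by
roughly the square root of the run count).  Because the real NI averages
importance over hundreds of iterations before the square root while the null
does not, the threshold is conservative, which matches the observed behavior
that panels without genuine signal flag nothing.

Cross-group displays min-max rescale the pooled 4 x regions NI values to
[0, 1] (numbers only; rendering is out of scope).  The **consensus map**
counts, per region, for how many of the three scores the region is
significant (0-3).

## Cohort statistics

One-way ANOVA is implemented both on raw vectors (scipy) and reconstructed
from per-group (n, mean, SD) summaries via `SSB = sum n_i (m_i − m)^2`,
`SSW = sum (n_i − 1) s_i^2` — the summary route reproduces published
demographic-table F statistics without subject-level data (rounding of the
printed summaries bounds agreement at roughly 0.1%).  Sex-by-diagnosis
contrasts use Pearson chi-squared without continuity correction, matching
printed values on 2 x 3 tables.  Pairwise biomarker comparisons of
per-iteration MSE vectors use Tukey's HSD (statsmodels) at FWER 0.01 with
the Tukey-Kramer unequal-n adjustment; since iteration vectors share
subjects and splits they are not independent, and the implementation logs
this caveat rather than pretending otherwise.

## Synthetic cohort generator

The generator emulates a three-cohort observational study:

- **Sample sizes, scores, ages, sex ratios** default to the published
  structural-MRI subsample summaries (n = 265/274/227; e.g. MMSE
  29.06 ± 1.18 / 27.63 ± 1.89 / 23.08 ± 2.67 for HC/MCI/AD).
- **Scores** are drawn from a clipped normal per (group, score).  Because a
  plain clip biases means near a bound (HC MMSE would shift by ~0.14, about
  2 standard errors at n = 265), the normal's location is solved so the
  post-clip expectation equals the configured mean; draws beyond 4 SD are
  redrawn first.  SDs are taken as printed (the clip shrinks them slightly).
- **Region values** are a per-region baseline (drawn once from N(1.0, 0.1);
  tree partitions are invariant to per-feature affine scaling, so absolute
  units are immaterial) plus optional planted effects plus N(0, 0.1) noise.
- **Planted effects** add `slope * z` to one region, where `z` is the score
  standardized over the whole cohort, only for subjects in the effect's
  active diagnosis groups — encoding the qualitative structure that
  region-score associations strengthen when the AD cohort is present.

The `planted` fixture uses two synthetic panels (30 and 10 regions).  Three
of the 30 regions each carry effects on all three scores, active in AD only,
with |slope| = 0.03 — calibrated once, on a 20x-scale cohort, so that a
planted region's univariate R² with each score is about 0.2 within the HC/AD
selection (roughly 0.15-0.2 in the other AD-containing groups, ~0 in
HC/MCI).  The generator does **not** model spatial covariance between
regions, longitudinal change, per-modality missingness, or non-linear
dose-response; recovery results on it therefore demonstrate that the
pipeline detects monotone group-dependent associations at realistic effect
sizes and sample sizes, not that it handles correlated-region attribution in
real parcellations (the surrogate-split machinery exists for that, and is
tested directly on duplicated/correlated columns instead).

## Execution profiles and problem sizes

The `paper` profile runs the full protocol (500 iterations, 500
permutations, 50 learners).  The `ci` profile is the package's desk-scale
default for tests and examples: 100 iterations, 100 permutations, 15
learners.  Recovery experiments in the test suite use 20 replicate cohorts
at the fixture's native sample sizes (HC/AD n = 492, 30 regions); the
acceptance script uses 6 replicates.  At these sizes NI estimates average
1,500 trees per cell, which pilot runs showed to be comfortably stable for
the planted effect sizes.

## Known limitations

- Surrogate routing is used for importance attribution only; prediction
  routes by primary splits (training data is complete by construction, so
  missing-value routing is out of scope).
- The permutation threshold is one scalar per cell; regions with atypical
  null variance are not individually calibrated (per-region variant behind
  a flag).
- "Mean + 2 SD" corresponds to the 97.7th percentile of a normal, not the
  95th; the parenthetically defined computation (mean + 2 SD) is
  implemented, as it is the operational definition.
- Bagging and random forests are spanned by one family via
  `mtry_fraction`; results for both configurations are first-class, and no
  hybrid aggregation of the two is defined.
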