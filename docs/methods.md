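# Methods

## The model

A binary classifier (or diagnostic score) yields a real score X and a
binary outcome Y. With F0 and F1 the conditional score cdfs of the
negative (Y=0) and positive (Y=1) class, thresholding at x gives
FPR(x) = 1 − F0(x) and TPR(x) = 1 − F1(x). When both cdfs are continuous
and strictly increasing, the ROC curve is the function

    R(p) = 1 − F1(F0⁻¹(1 − p)),   p ∈ (0, 1),  R(0)=0, R(1)=1.

A **Bi-distributional ROC model** chooses a parametric family for each
class, fits both by maximum likelihood, and plugs the fitted cdfs into R.
The package supports seven families — Normal(μ, σ); Exponential(μ),
mean-parameterized; Weibull(α shape, β scale); Gamma(α shape, β rate);
minimum-type extreme value EV(μ, σ); GEV(k, σ, μ); and generalized Pareto
GP(k, σ) with location fixed at 0 — and all 16 positive/negative family
pairings of the candidate portfolio (the 7 matched pairs plus 9 mixed
ones). AUC is the integral of R over [0, 1], computed by adaptive
Gauss–Kronrod quadrature to absolute tolerance 1e-8.

## The criteria

Because FPR and TPR are dependent, the curve's point set is summarized by
a standardized bivariate Gaussian with correlation matrix
R₂ = [[1, r], [r, 1]], where r is the Pearson correlation of the (FPR,
TPR) points. The inverse Fisher information matrix of that model is block
diagonal:

    F̂⁻¹ = blockdiag( R₂ , (2/n) D₂⁺ (R₂ ⊗ R₂) D₂⁺ᵀ ),

with D₂⁺ the Moore–Penrose inverse of the duplication matrix (the map
from vech to vec of a symmetric matrix) and n = n₁ + n₂ the total sample
size. With s = rank(F̂⁻¹) = 5 and the maximal entropic complexity
C1(A) = (s/2)·log(tr A / s) − (1/2)·log det A, the criteria are

    ICOMP-ROC = n·(log 2π + log|R₂| + 1) + 2·C1(F̂⁻¹)
    AIC-ROC   = n·(log 2π + log|R₂| + 1) + 2·rank(R₂).

Both are minimized over candidates. Useful closed forms, used as
independent cross-checks of the assembled matrix (never as the primary
path): tr F̂⁻¹ = 2 + (5 + r²)/n and |F̂⁻¹| = 4(1 − r²)⁴/n³.

### Structural consequences worth knowing

Two properties follow directly from the definitions and shape everything
downstream.

1. **The two criteria rank candidates almost identically.** Their
   difference, 2·C1(r, n) − 4, depends only on (r, n); expanding C1, the
   ICOMP-ROC coefficient on log(1 − r²) is n − 4 versus n for AIC-ROC.
   Divergent selections between them are only possible among candidates
   whose r values are extremely close.
2. **Both criteria reward |r| → 1, i.e. the most *linear* (FPR, TPR)
   point set.** A near-diagonal curve — a nearly uninformative candidate —
   has r ≈ 1 and drives n·log(1 − r²) toward −∞. For candidate portfolios
   in which some pair produces a near-diagonal curve (e.g. when the two
   classes are nearly indistinguishable, so matched-family pairs fit
   near-identical marginals), that pair wins regardless of how well it
   fits the data. The criteria contain no likelihood term for the fitted
   marginals, so goodness of fit enters only indirectly through the curve
   shape. The Monte Carlo results below make this concrete.

## Numerical choices

* **Quantiles and sampling**: closed forms where the family has one;
  numeric inversion (scipy) for Normal/Gamma; inverse-transform sampling
  with uniforms clipped to [1e-16, 1 − 1e-16].
* **MLE.** Weibull: the profile shape equation solved by Brent bracketing
  to xtol 1e-13 (log-domain rescaling prevents overflow), scale from the
  shape; the returned estimate satisfies both score equations to < 1e-8.
  Gamma: the digamma shape equation solved the same way with the
  classical closed-form start; rate = shape / mean. Normal and
  Exponential are closed form (σ with divisor n). EV/GEV/GP use numeric
  likelihood maximization; GP's location is pinned at 0, so those three
  positive-support families (and Exponential/Weibull/Gamma) are
  *fit-infeasible* on samples containing non-positive values and are
  excluded from a run rather than aborting it. Constant samples flag
  `converged=False` with σ floored at 1e-12.
* **Correlation point set.** For parametric candidates the default
  evaluates the fitted curve at the pooled sample's order statistics
  (threshold-indexed, data-dependent, m ≈ n points plus endpoints); a
  uniform 512-point grid is available via `CriterionConfig(point_set="grid")`.
  For classifiers, the empirical ROC points of the out-of-fold scores are
  used directly. |r| is clamped at 1 − 1e-10 so log-determinants stay
  finite; beyond float resolution of the small IFIM block the analytic
  determinant takes over.
* **Lack-of-fit bracketing.** The default reads the criterion as
  n·(log 2π + log|R₂| + 1); `CriterionConfig(l0_form="bivariate")` selects
  the full bivariate-Gaussian constant n·(2 log 2π + log|R₂| + 2). The two
  differ by a constant at fixed n, so rankings are identical — the switch
  exists to make the choice auditable.
* **Ties** in winner selection break to the earlier candidate in the
  canonical portfolio order and are flagged.

## Monte Carlo study conditions

Class sizes are 200 (negative) and 300 (positive); child seed = master
seed + run index. Two scenarios ship as presets:

* **Normal–Normal**: positive N(1, 1.87), negative N(0.99, 0.71) — nearly
  equal means, unequal spreads, so the classes are close to
  indistinguishable (true AUC ≈ 0.50) and the Gaussian draws exclude the
  positive-support candidates in every run.
* **Weibull–Gamma**: positive Weibull(shape 2, scale 1), negative
  Gamma(shape 2, rate 2). These two distributions are themselves nearly
  identical (true AUC ≈ 0.46), which is the stressful regime of
  consequence (2) above.

Measured behavior over 25 seeded runs (reproduced by
`scripts/acceptance.py` and the acceptance tests):

* Identical-class pairs give quadrature AUC 0.5 to 1e-8, and binormal
  pairs match Φ(Δμ/√(σ0² + σ1²)) to 1e-7.
* Weibull–Gamma scenario: maximal AUC selects Weibull–Exponential in
  25/25 runs. AIC-ROC and ICOMP-ROC select Exponential–Exponential in
  ~23/25 runs, *not* the generating Weibull–Gamma pair: the matched
  exponential fits produce the straightest pooled-threshold point set
  (r ≈ 0.9987 vs ≈ 0.9974 for Weibull–Gamma), exactly as consequence (2)
  predicts. Neither the grid point set nor the alternative lack-of-fit
  bracketing changes this (the latter cannot, being rank-preserving).
* Normal–Normal scenario: ICOMP-ROC selects Normal–Normal in ~14/25 runs
  at n = 500, with GEV–GEV and EV–EV taking the rest — three near-tied
  curve shapes whose r values differ in the third decimal. At
  n₁ = n₂ = 5000 the Gaussian truth ranks first in 10/10 runs (the weak
  consistency check in the test suite), so the 56% rate is a
  small-sample resolution limit, not a coding artifact.

Larger recovery rates for the generating pair would require either
well-separated study conditions or a criterion that includes the fitted
marginals' likelihood; both are outside this package's definition of the
criteria, so the measured rates are reported as-is.

## Classifier evaluation

Stratified 5-fold cross-validation produces out-of-fold positive-class
probabilities; hard labels threshold at 0.5. Five classifier families are
wrapped at library defaults (logistic regression with an enlarged
iteration cap; SVC with Platt scaling; Gaussian naive Bayes; 5-NN;
decision tree). Metrics with empty denominators are NaN plus an
`undefined` flag, never 0. The criteria use n = number of instances.

Consequence (2) applies verbatim here: a near-random classifier's
empirical ROC hugs the diagonal, so ICOMP-ROC and AIC-ROC are *smaller*
for weaker classifiers on the same data. They remain useful for comparing
candidate ROC *models* of one score set, but make degenerate objectives
for feature selection.

## Genetic algorithm

Binary masks over feature columns; Bernoulli(0.5) initialization with
all-zero repair; roulette selection on tie-averaged rank weights (raw
criteria are unbounded below); GA1 = single-point crossover at rate 0.8
with mutation 0.3, GA2 = a deterministic single-point → two-point →
uniform cycle at rate 0.6 with mutation 0.001; elitism 1; fitness
evaluations cached by mask. **The default objective is negated
cross-validated AUC**, not ICOMP-ROC: by the paragraph above, minimizing
ICOMP-ROC over masks provably converges on noise subsets (measured:
noise-only mask ≈ −1557 vs informative-only ≈ +1383 on the planted
table), and an objective that anti-selects signal would make the selector
useless. The criteria remain available as objectives for users who want
to study exactly that behavior. On the planted-signal table (5
informative of 30 features, effect size 2σ) a reduced-budget run
(20 generations, population 40) recovers ≥ 4 of the 5 planted features in
10/10 seeds.

## Synthetic data

`make_feature_table` emulates a breast-cancer-diagnostic-shaped table:
569 instances, 30 standard-Gaussian features, 37% positive class, the
first `n_informative` columns mean-shifted by `effect_size`·σ in class 1.
It does not emulate feature correlations, heavy tails, or measurement
scales of real diagnostic features, so passing tests demonstrate
recovery of independent additive mean shifts only. `make_score_labels`
draws per-class scores from any two families at the study sizes.

## Known limitations

* No censored-data likelihoods, Bayesian fitting, partial AUC, ROC
  confidence bands, or multi-class extensions.
* The criteria's dependence on the correlation point-set recipe is
  intrinsic; both shipped recipes (pooled thresholds, uniform grid) are
  documented and configurable, and absolute criterion values should not
  be compared across recipes.
* GEV and GP fits on small samples can sit on the boundary of their
  usual asymptotics (k near −0.5); estimates are reported with
  `converged` flags rather than filtered.
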