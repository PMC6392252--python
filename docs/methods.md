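# Methods

## Model and estimation chain

`iccmix` fits a K-component Gaussian mixture of sparse linear regressions
to small-n-large-p data. The density of each response is
f(y|θ) = Σ_k π_k φ(y | x'β_k, σ_k²) with θ = (β_1..K, σ_1..K, π_1..K) and
each β_k sparse. Estimation treats the latent component memberships as
missing data and alternates stochastic imputation with blockwise
re-estimation (the imputation-conditional consistency scheme):

1. **I-step.** Each sample's label is drawn from the membership posterior
   P(τ_i = k | θ) ∝ π_k φ(y_i | x_i'β_k, σ_k²), evaluated in log space and
   normalized in probability space after subtracting the row maximum (the
   usual log-sum-exp normalization silently loses the normalizer when the
   log-weights are astronomically negative; rows where every component has
   exactly zero density fall back to uniform with a logged warning).
2. **CC-step.** For each imputed cluster χ_k: π_k = |χ_k|/n (exact counts,
   so Σπ_k = 1 at every iteration); β_k by SIS-MCP on the member rows;
   σ_k² = RSS_k / (|χ_k| − Card(β_k) − 1), with denominator 1 when the
   corrected denominator is nonpositive.

The label and parameter sequences form two interleaved Markov chains. A run
records, per iteration, the label vector, the fitted model and a BIC value;
defaults are T = 500 iterations with t₀ = 100 discarded as burn-in, which is
generous — the chain typically equilibrates within a few tens of iterations.
Initialization is a uniformly random partition; k-means-style warm starts
are deliberately not used.

## Per-component sparse fits (SIS-MCP)

- **Screening.** Features are ranked by absolute marginal Pearson
  correlation with the response; the top d = ⌊m/log m⌋ survive, with m the
  component's sample count. Ties break toward the smaller index; constant
  columns score 0. A rank-based (Spearman) variant, `model_free_screen`, is
  provided for pre-screening very wide expression matrices; it is a generic
  marginal utility, not a reimplementation of any particular published
  screener.
- **MCP path.** On the survivors, minimax-concave-penalized least squares is
  solved by cyclic coordinate descent with covariance updates, JIT-compiled
  with numba. Columns are standardized to mean 0 and x'x/n = 1 internally;
  results are reported on the original scale with an unpenalized intercept.
  Concavity γ = 3 (the literature's standard default; any γ > 1 is
  accepted). The λ grid has 100 log-spaced values from λ_max down to
  10⁻³·λ_max, warm-started downward. Convergence: max coefficient change
  ≤ 10⁻⁷ per sweep or 1000 sweeps; non-converged path points are flagged
  and logged, never dropped.
- **λ selection.** The path solution minimizing the extended BIC
  n·log(RSS/n) + Card·log n + 2γ_e·log C(p, Card), with γ_e = 0.5 and p the
  *original* feature dimension. The extended term matters: screening keeps
  the features most chance-correlated with the response, so the plain BIC
  is anti-conservative after screening — with it, pure-noise designs
  acquired 3–5 spurious features in most runs; with the extended term they
  select at most a couple in ≥ 95% of runs while recovery of strong signals
  is unaffected. γ_e = 0 restores the plain BIC.
- Clusters below 10 samples get an intercept-only fit with an empty
  selected-variable list (tiny clusters carry too little information for
  variable selection; this also reproduces the observed behaviour of the
  method on real expression data, where 2-sample clusters select no genes).

## Chain stability

Three degeneracies of the naive chain were identified on the benchmark
design and are handled explicitly:

- **Density spikes.** A tiny cluster with a near-perfect fit drives σ_k to
  the floor and becomes a spike that permanently captures its own members —
  an absorbing state. σ_k is therefore floored at max(10⁻⁴, 0.05·sd(y)).
- **Absorbing empties.** Under exact count updates an empty component has
  π_k = 0 and can never regain members, contradicting the ergodicity the
  averaging rests on. An empty component is rescued by seizing the 10
  samples the current model explains worst (lowest mixture log-density).
- **Stuck modes.** A start can settle into a mode where one component
  absorbs two true groups while another idles as a parasitic near-empty
  cluster. A component needing more than 8 rescues, or sitting below the
  minimum cluster size for more than 50 consecutive iterations, marks the
  start as collapsed; the chain restarts from a fresh random partition
  (drawn from the same seeded stream — runs stay reproducible). After 5
  failed restarts `run_icc` raises a collapse error suggesting a smaller K,
  while `select_K` instead completes a final chain with collapse detection
  disabled so that an overfitted K still receives an average BIC — the
  struggling chain's inflated BIC is precisely what disfavors that K.
  On real data where persistent tiny clusters may be genuine, set
  `max_small_streak=None`.

## Choosing K: average BIC

For each candidate K an independent chain is run (deterministic sub-seed
per K derived from the master seed) and the BIC recorded each iteration;
the criterion is the mean over the post-burn-in window, and the smallest K
among minimizers wins (parsimony on ties). The recorded BIC is, by
default, the **observed-data (mixture-likelihood)** form
−2 Σ_i log Σ_k π_k φ(y_i|·) + df·log n with
df = Σ_k (Card(β_k)+2) + (K−1). A complete-data form (likelihood of the
assigned labels) is available as `bic_form="complete"` but is not the
default: adaptively imputed labels buy a redundant component roughly
0.2–0.3 nats per sample of assigned-label likelihood, which outweighs the
log n penalty and biases the complete-data criterion toward larger K
(measured directly on homogeneous data, where it preferred K=2 to K=1).
The normalizing constant divides by the number of retained iterations; the
averaging window is t₀+1..T.

## Consensus aggregation

Different iterations select different variables, so the post-burn-in label
chain is reduced to one partition before the final fit: the dissimilarity
d_ij counts the retained iterations in which i and j carry different
labels (raw counts, normalized only for plotting), is clustered by
average-linkage agglomeration (scipy) and cut at K. Ties in the linkage are
resolved by the implementation's fixed scan order — deterministic given D,
which is what reproducibility needs. The final reported estimator refits
each consensus cluster: π_k from cluster sizes, β_k by SIS-MCP, σ_k by the
degrees-of-freedom-corrected residual s.d. An averaged chain estimator
(`average_model`) is also provided: post-burn-in models are aligned to the
final iteration's model by the permutation minimizing summed ℓ₂ distance
between coefficient vectors (exhaustive over K! for K ≤ 6) and averaged
componentwise.

## Prediction

Three modes, differing in how a new sample is assigned to a component:

- `posterior-with-response` — argmax of the membership posterior evaluated
  *with the observed test response*, then predict from that component's
  regression. This is the rule the benchmark prediction tables use; note
  that it leaks the test outcome into the cluster assignment, so its
  accuracy reflects conditional prediction given a resolvable membership,
  not pure forecasting.
- `mixture-mean` — E[y|x] = Σ_k π_k (b0_k + x'β_k); no response access.
- `max-prior` — always the largest-π component.

Reports carry Pearson correlation and RMSE against the observed test
response when available.

## Evaluation metrics

Variable selection and clustering are scored as binary decisions:
fsr = FP/(TP+FP), nsr = FN/(TP+FN). For per-component scores the estimated
components are first aligned to the truth by the ℓ₂-minimizing permutation
of coefficient vectors; for true component k, TP counts correctly assigned
samples, FP intruders, FN escapees. Coefficient accuracy is the Euclidean
norm ‖β̂_k − β_k‖ (intercept included). Method comparisons across datasets
use Fisher's z = ½log((1+r)/(1−r)) per correlation and a paired t-test on
the per-dataset z differences (p = 1 when all differences vanish).

## Synthetic data

The generator emulates the benchmark designs: K = 3 components of 200
samples each (deterministic block assignment, so empirical proportions are
exact), p = 2000 features, predictors i.i.d. N(μ·1, I_p) with one common
mean μ ~ U(0,1) per dataset (a per-column-μ variant is provided), σ_k = 1,
and three slope coefficients of 3 per component — feature 0 shared by all
components, pairs {1,2}, {3,4}, {5,6} exclusive; intercepts 0. The support
positions are exchangeable under the i.i.d. predictor law. A p=200 variant
serves the lower-dimensional comparison design, and a single-component
configuration (default n=150, p=100 — sized so a ten-replicate selection
scan over K ∈ {1,2,3} stays cheap) serves null-K experiments.

What the generator does **not** emulate: correlated predictors (gene
coexpression), non-Gaussian or heteroscedastic noise, covariate-dependent
mixing proportions, or measurement artefacts of expression data. Passing
tests on this generator demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness on real data.

### An intrinsic limit of the benchmark design

Under the stated design the components overlap substantially: for a sample
from component k, the competing conditional means differ by x'(β_k − β_j)
~ N(0, 36) while σ = 1, and the resulting Bayes-optimal clustering error —
assigning by posterior argmax with the *true* parameters — averages ≈ 0.196
across datasets (≈ 0.19 analytically). No estimator can beat this floor on
average. The consensus partition lands within about 0.01–0.02 of it
(clustering fsr/nsr ≈ 0.18–0.22 per component), and the residual
contamination propagates: consensus clusters contain ~20% of samples from
other components, which (a) biases σ̂_k away from the generating value —
typically downward, since each ambiguous sample lands in whichever
component happens to explain it best, shrinking within-cluster residuals —
(b) occasionally drags another component's true feature into a cluster's
selected set (its effective slope in the contaminated cluster, ≈ 0.2·3, is
genuinely nonzero there), and (c) leaves coefficient errors around
0.10–0.3 per component. Selection nsr is 0 in every replicate observed.

## Numerical choices

- Coordinate updates are exact for γ > 1 on standardized columns
  (firm-thresholding closed form); orthonormal designs reproduce the
  coordinatewise rule to 10⁻⁸.
- RSS is floored at n·10⁻¹² inside information criteria to keep perfect
  fits finite; ties along the λ path resolve to the largest λ (sparser
  fit).
- Posterior sampling uses inverse-CDF draws against row-wise cumulative
  sums; all randomness flows through `numpy.random.Generator` objects
  seeded from a single master seed via `SeedSequence` spawning, so adding
  a pipeline stage never perturbs another stage's stream.
- Exhaustive K! permutation matching is used for component alignment
  (K ≤ 6); larger K would need a Hungarian assignment, out of scope here.

## Known limitations

- The average-BIC scan refits the full chain per candidate K; cost is
  linear in |K_grid|·T.
- The posterior-with-response prediction mode should not be read as a
  forecasting benchmark (see above); use `mixture-mean` for honest
  out-of-sample prediction without response access.
- Vanilla SIS only; iterative screening (ISIS) is an extension point.
  SCAD and adaptive-lasso penalties are not implemented; the penalty
  interface is pluggable.
- No handling of missing predictor values; rows with missing cells are
  rejected at ingestion.
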