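# Methods

This note documents the models, the simulator, the numerical choices and the
limitations of `gptk`. Notation: n individuals, m markers, X the n × m
dosage matrix counting A1 alleles, y the trait vector.

## Quality control and imputation

Filters run in a fixed order: (1) individuals with more than
`max_missing_per_individual` missing calls (default 10%) are removed;
then markers by (2) call rate < 95%, (3) minor allele frequency < 5%
(frequencies recomputed after individual removal), (4) a 1-df chi-square
Hardy–Weinberg test at p < 10⁻⁶. All four thresholds are parameters
(`QCParams`) because sensible values differ across panels (MAF cuts of 1–5%
and HWE cuts of 10⁻⁶–10⁻⁴ are all in routine use). The HWE statistic is the
plain chi-square of observed genotype counts against p², 2pq, q² at the
marker's own allele frequency; an exact test is deliberately not provided.
Surviving missing dosages are imputed to the marker mean (2p̂), the
conventional choice when the matrix feeds a relationship matrix or kernel.
`qc_filter` is idempotent: imputed values equal the column mean, so
re-running it changes nothing.

## Predictors

**KRR.** The ridge objective penalizing squared errors with weight C has the
dual solution w = (K + αI)⁻¹y with α = 1/C; the implementation exposes α
directly, which is also the quantity tuners search (uniform 0–10; samples at
exactly 0 are clamped to 10⁻⁸ before the solve). The system is solved by
Cholesky factorization; with α = 0 a singular K raises an error advising
α > 0. Prediction is k′w by the representer theorem — the primal weight
vector is never formed.

**SVR.** The ε-insensitive dual is solved in the stacked variables
a = (α, α*) ∈ [0, C]²ⁿ: minimize ½aᵀQa + pᵀa subject to zᵀa = 0, with
z = (+1…, −1…), p = (ε − y, ε + y), Q = zzᵀ ∘ K̃. The solver is sequential
minimal optimization with maximal-violating-pair selection (the same
working-set rule LIBSVM uses), analytic two-variable updates, KKT tolerance
10⁻³ and a cap of 10⁴ pair updates; hitting the cap raises an error carrying
the final KKT violation. Extreme hyperparameter draws (e.g. C near 100 with
a near-degenerate kernel) can legitimately hit the cap — during tuning such
trials are recorded with +∞ loss and the search routes around them, which
mirrors how SVR genuinely fails on some traits. ε is fixed at 0.1 on
z-scored responses rather than tuned; responses are z-scored per training
fold for both KRR and SVR and predictions are transformed back.

**GBLUP.** G = ZZ′ / (2Σpᵢ(1−pᵢ)) with Z = X − 2p, allele frequencies p
taken from the panel the matrix is built on. For prediction of new
individuals the cross-block uses the *training* frequencies and denominator.
REML: with G = UDUᵀ computed once, rotate y and the intercept column by Uᵀ;
for each λ = σe²/σg² the GLS mean, σ̂g² and the restricted likelihood are
O(n) expressions in the rotated coordinates. λ is profiled on a 41-point
log grid over [10⁻⁶, 10⁶] and refined by bounded scalar minimization
(Brent, xatol 10⁻⁸ in log λ); a boundary solution emits a warning. GEBVs
solve (G + λI)u = y − μ̂, ĝ = Gu; validation individuals get
μ̂ + G_cross (G + λI)⁻¹(y − μ̂). The identity "GBLUP = KRR with K = G and
α = λ̂ on centered y" is enforced by test.

**PCA reduction (KRR/SVR only).** Features are reduced by PCA fitted on the
training rows of each split; the component count k is a tuned
hyperparameter with range 1…min(n_train − 1, m), resolved at tuning time.
The decomposition is computed once at full rank and truncated by column
slicing, which is mathematically identical to refitting at each k and makes
a 50–200-trial search affordable. Component signs are fixed (largest
loading positive) so results are reproducible.

## Hyperparameter optimization

The search space is a forest: `gamma` exists only for the RBF (and
polynomial) kernel, `degree` only for polynomial. Three strategies share
it; all minimize loss = −(Pearson accuracy).

TPE: after `n_startup = 20` prior-sampled trials, the history is split at
the γ = 0.25 quantile of loss (n_good = max(1, ⌈γn⌉), ties to the earlier
trial). Per parameter, the good and bad observations each get an adaptive
Parzen density: a mixture of one truncated Gaussian per observation plus one
prior-wide uniform component, all equally weighted; the bandwidth of each
component is the larger of its distances to its sorted neighbors (domain
bounds included), floored at 1% of the range. Log-scale parameters are
modeled in log space; integer parameters discretize the continuous mixture
onto the integer grid; categoricals use unit prior counts plus observation
counts, normalized. Each iteration draws `n_candidates = 24` configurations
from the good densities and evaluates the one maximizing
Σ log l(x) − log g(x) over its active parameters — the density ratio is
monotone in expected improvement, so maximizing one maximizes the other.
γ, n_startup and n_candidates are conventional TPE settings, exposed on
`TPEConfig`. With γ = 1 (no bad trials) the proposal degenerates to a draw
from the all-observation density. Failed objective evaluations are recorded
as +∞ and never abort the search. All strategies are deterministic given
their seed.

Default spaces: KRR — kernel ∈ {cosine, rbf, linear}, α ∈ [0, 10], RBF γ
log-uniform on [10⁻⁶, 10⁻³], k ∈ [1, n]. SVR — kernel ∈ {rbf, linear,
poly}, degree ∈ {1, 2, 3, 4}, the same γ range, C log-uniform on
[0.1, 100], k ∈ [1, n]. The γ range is kept as stated even though it is
scale-sensitive against PCA scores of dosage data (it makes the RBF kernel
nearly flat there, so the cosine/linear kernels usually win); the
polynomial kernel is (γ·xᵀx′ + 1)^degree with the constant fixed at 1.

## Evaluation protocol

`run_cv` runs n_repeats × n_folds (default 10 × 5 = 50 replicates) outer
cross-validation. Within each training split, tuning sees only that split:
the objective is the Pearson accuracy averaged over `n_inner_splits = 3`
seeded 80/20 holdouts of the training split, the best configuration is
refit on the whole split, and the held-out fold is touched exactly once.
A single inner holdout (the minimal choice) proved noticeably noisy at
desk-scale budgets: ranking ~50 configurations on one ~100-sample holdout
picks lucky configurations (winner's curse) and cost tuned KRR several
accuracy points against GBLUP; averaging three holdouts removed most of
that gap while staying strictly inside the training split. The count is a
protocol parameter. GBLUP has no tuned hyperparameters and skips the inner
stage. Folds where a model cannot be fitted or predicts a constant score 0
with a warning rather than aborting — the analogue of a method being
"not applicable" to a trait. Everything (folds, inner splits, tuner) is
deterministic given the protocol seed; a leakage test asserts that
perturbing held-out phenotypes leaves fitted models bit-identical.

Method comparison: per-trait mean accuracies form a traits × methods
matrix; within each row methods are ranked (rank 1 = most accurate, ties
averaged); χ²_F = 12N/(k(k+1))·[ΣR̄ⱼ² − k(k+1)²/4] with k − 1 df; the
Nemenyi critical difference is CD = q_α √(k(k+1)/6N) with q from the
studentized-range table (k = 2…10, α ∈ {0.05, 0.10}, hardcoded and
cross-checked against scipy's studentized-range distribution).

## Simulator

Genotypes are independent loci: per-marker allele frequency drawn uniformly
from `maf_range` (default 0.05–0.5, a post-QC-like spectrum), dosages
binomial(2, p), markers assigned evenly to chromosomes (defaults: 5
chromosomes, 10,000 markers, 4,000 individuals of which the first 3,000
form the reference generations). Traits are strictly additive: `n_qtl`
markers (default 100; 60 in the evaluation runs) drawn without replacement,
effects standard normal, genetic values centered, and Gaussian noise scaled
from the realized genetic variance so var(g)/var(y) equals the target h²
in expectation. The generator returns the QTL set, effects, genetic values
and realized h² for recovery tests; (seed, config) fully determine all
outputs.

What the simulator does *not* emulate: linkage disequilibrium, pedigree
structure, dominance/epistasis, genotype-by-environment interaction, or
selection. None of the implemented estimators requires LD to be exercised,
but its absence matters quantitatively: with independent loci the number of
effective chromosome segments equals the marker count, so prediction
accuracies at a given (n, m, h²) sit well below what panels with LD reach
at the same size. Concretely, at n = 1000, m = 2000, h² = 0.45 the
cross-validated GBLUP correlation with phenotypes averages ≈ 0.28
(matching the Daetwyler expectation √(nh²/(nh² + m)) · √h²), whereas real
panels of similar size print ≈ 0.4. Passing tests therefore demonstrate
correctness and calibration of the machinery, not the absolute accuracy
levels attainable on real data.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` size their simulations so a full
run stays in the minutes range on one CPU: REML recovery uses one simulated
panel per heritability level (n = 1000, m = 2000) with 100 phenotype
replicates sharing the panel's eigendecomposition — the replicated
randomness is the trait, which is what REML estimates from; cross-validated
comparisons use n = 600–1000 with 5-fold CV repeated twice and tuning
budgets of 50; the TPE benchmark uses the full 200-evaluation budget over
20 seeds. The SVR-vs-QP oracle checks run at n ≤ 20 where a dense SLSQP
solve is exact.

## Known limitations

- SVR at the tolerance/iteration defaults is the slowest component; large C
  with flat kernels converges slowly by design of the cap.
- The REML profile assumes a single genetic variance component and an
  intercept-only fixed effect; covariates must be pre-corrected out of y*.
- The Nemenyi table covers 2–10 methods at α = 0.05/0.10 only.
- Grid search enumerates the full conditional product; grids over many
  parameters grow multiplicatively.
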