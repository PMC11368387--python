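# Methods

## Model

`lucidpy` fits a joint latent-cluster model linking three data blocks
measured on the same n subjects: an exposure matrix G (n×p, complete), an
omics matrix Z (n×m, possibly missing by cell or by whole row) and a
continuous outcome Y (n, complete).  A discrete latent variable X with K
categories mediates all dependence:

    X_i | G_i        ~ Multinomial(softmax(beta' [1, G_i]))
    Z_i | X_i = j    ~ MVN(mu_j, Sigma_j)
    Y_i | X_i = j    ~ N(gamma_j, sigma2_j)

The softmax row for the reference cluster (cluster 0, and after relabelling
the cluster with the smallest gamma) is fixed at zero, so exp(beta_jk) is
the odds ratio of membership in cluster j per unit of exposure k.  The
observed-data log-likelihood is the usual mixture form

    l(Theta) = sum_i log sum_j S(X_i=j | G_i; beta)
                             * phi(Z_i | mu_j, Sigma_j)
                             * phi(Y_i | gamma_j, sigma2_j).

Exposures are conditioned on, not modelled, which matches prospective
sampling; Y here is continuous (a binary-outcome variant is out of scope).

### Covariance families

Sigma_j can be constrained through the eigenvalue-decomposition
parameterization Sigma_j = lambda_j D_j A_j D_j'.  Four of the resulting
families are implemented — EII (one spherical matrix shared by all
clusters), VII (spherical, per-cluster volume), EEE (one full matrix
shared) and VVV (unconstrained per cluster, the default) — because these
four span the volume/shape/orientation axes while keeping every M-step in
closed form.  Each estimated matrix receives a ridge of
1e-6 × mean(diagonal) × I before any inversion; near-empty clusters in
small simulated samples otherwise produce numerically singular matrices.

## Missing omics data

Rows of Z are partitioned by missing pattern: `ia` (fully observed), `ib`
(sporadically missing, ≥1 but <m cells) and `ic` (list-wise missing, all m
cells).  The mask is explicit and authoritative — imputed values never
overwrite the record of which cells were observed.

* **List-wise rows** contribute only their exposure and outcome terms.
  Their responsibilities use S·phi(Y) and the likelihood partition drops
  phi(Z) for them entirely.  mu_j and Sigma_j are therefore estimated from
  `ia ∪ ib` rows only, while beta, gamma and sigma2 use every row.
* **Sporadic cells** are initialized by iterative column-regression
  imputation (5 sweeps of regressing each incomplete column on the others,
  starting from column means; with fewer than two complete rows the column
  means are kept) and then refreshed every iteration by an I-step.

### The I-step and its weights

For a row with observed block a and missing block b, the missing block is
replaced by the solution of the stationarity condition of the weighted
Gaussian log-density, expressed through blocks of the precision matrix
Lambda_j = Sigma_j^{-1}:

    Z_b <- [sum_j w_j Lambda_j^bb]^{-1}
           sum_j w_j (Lambda_j^ba mu_a + Lambda_j^bb mu_b - Lambda_j^ba Z_a)

with w_j proportional to r_j · phi(Z_i | mu_j, Sigma_j) evaluated at the
row's current imputation, normalized over j (the solution is invariant to
rescaling the weights; normalization prevents underflow, and if every
weight underflows even in log space the dominant cluster alone is used).
At K=1 the formula collapses algebraically to the Gaussian conditional
mean mu_b + Sigma_ba Sigma_aa^{-1}(Z_a − mu_a).

The choice of r_j matters.  This implementation passes the *Z-free*
responsibility — softmax times outcome density, normalized — evaluated at
the freshly updated parameters.  The product w_j is then exactly the row's
posterior responsibility at (Theta_new, Z_current), which makes the I-step
an exact minorize–maximize update of the observed-data likelihood: the
mixture log-likelihood cannot decrease.  The tempting alternative of
reusing the E-step responsibilities (which already contain the previous
iteration's Z density) double-counts the Z term; in experiments it produced
occasional log-likelihood drops around 1e-2, and it has no MM
interpretation.  Monotonicity is still monitored at run time: any decrease
beyond 1e-6 flags the fit as non-converged.

## Fitting loop

Each outer iteration runs E-step (responsibilities), M-step (beta by
L-BFGS on the responsibility-weighted multinomial log-likelihood with
analytic gradient, gradient tolerance 1e-6, at most 100 inner iterations,
warm-started from the previous beta; Gaussian and outcome blocks by
weighted moments), I-step, then the partitioned log-likelihood.
Convergence is declared when the absolute change falls below `tol`
(default 1e-6, relative mode available); the default iteration cap is
1000.  Degenerate clusters (effective weight below 1e-6·n) abort a
restart; `n_init` seeded k-means restarts are available and the best final
log-likelihood wins.  After convergence clusters are relabelled in
increasing order of gamma — the likelihood is label-invariant, and a
deterministic order is needed for reporting and for aligning estimates to
a simulation truth.

Initialization: sporadic cells filled as above; k-means (seeded) on the
filled `ia ∪ ib` rows gives hard labels; mu, Sigma from per-cluster
moments; beta from a multinomial-logistic fit of the labels on G; gamma,
sigma2 from per-cluster moments of Y with list-wise rows assigned (for
initialization only) to their most probable cluster under the fitted
softmax.

K is chosen by grid search on BIC = −2·loglik + d·log(n) with d the free
parameter count ((K−1)(p+1) + K·m + family-specific covariance count + 2K).
The BIC sample size is the full n, including list-wise missing rows, since
those rows contribute likelihood terms.

Outcome variance is cluster-specific.  A floor of 1e-8 guards sigma2
against exact degeneracy (warned, not silently absorbed).

## Baselines

Two naive strategies are provided for comparison: `complete_case` (drop
every row with any missing omics cell; refuse to run with fewer than 10·K
complete rows) and `mean_impute` (fill every missing cell, including whole
missing rows, with its column mean, then fit as complete).  With no
missingness both are numerically identical to the integrated fit.

## Synthetic data

The generator draws G as iid standard normal, X from the softmax, Z and Y
from the cluster Gaussians.  The reference design is n=10000, p=10, m=4,
K=2, split once into 8000 training and 2000 validation rows; replicated
benchmarks subsample 2000 training rows per replicate.  The reference
parameter values are fixed and versioned: cluster 2 loads 0.3 log-odds on
the first five exposures (none on the rest, intercept 0), cluster means of
Z at ∓0.5 with identity covariance, outcome means ∓1 with unit variance.
These produce detectable but realistic effects — the posterior computed
from the true parameters separates the clusters with AUC ≈ 0.93 — and are
overridable wherever a truth is accepted.

Missingness injectors: `listwise_mcar` blanks an exact quota of
round(ratio·n) uniformly chosen rows (exact, not Bernoulli, so replicate
missing counts are deterministic); `listwise_mar_y` draws the quota
without replacement with probability increasing in Y, scaled so the top
Y-quartile's selection odds are about 3× the bottom's (a
missing-at-random mechanism, since Y is observed); `sporadic_mcar` masks
cells iid Bernoulli(ratio), and rows that lose every cell are reclassified
as list-wise.

What the generator does *not* emulate: correlated or heavy-tailed omics
features, non-Gaussian outcomes, missingness depending on unobserved
values (MNAR, e.g. limit-of-detection censoring), or exposure measurement
error.  Passing benchmarks therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to their violation.

## Evaluation

Out-of-sample posteriors use G and the observed part of Z only (rows with
partial Z use the Gaussian marginal on the observed coordinates; fully
missing rows fall back to the softmax), never the outcome — predicting
cluster membership without Y is the use case.  Outcome predictions are
posterior mixtures sum_j r_ij·gamma_j.  Clustering accuracy is the rank
(Mann–Whitney) AUC of the high-outcome cluster's posterior inclusion
probability against the known simulated labels, computed with tie
correction.  Estimates are aligned to the truth by increasing gamma
(falling back to minimal total mu distance under gamma ties) before
aggregation.

The replication driver simulates one master cohort, splits it once, and per
replicate subsamples the training set, injects missingness at each ratio in
the grid, fits each requested method and scores it.  Study sizes used by
the shipped checks: 50 replicates for bias summaries, 30 replicates for
the three-method ordering benchmark, 20 seeded datasets for monotonicity,
20 replicates for BIC selection — sizes chosen so each check completes in
minutes while keeping Monte-Carlo error well below the effect sizes being
verified (300 replicates are available by flag).

## Known limitations

* Binary outcomes, covariate adjustment of the G→X or X→Y links, L1
  variable selection and bootstrap confidence intervals are not
  implemented.
* MNAR/limit-of-detection missingness is not modelled; sporadic
  missingness is handled under MCAR/MAR assumptions only, and real
  sporadic missingness frequently violates them.
* The EM objective is multimodal; a single k-means start can land in a
  local optimum on weakly separated data (use `n_init`).
* Exact-quota list-wise masking means the injected ratio is deterministic
  per replicate, which slightly understates the variability a Bernoulli
  mechanism would add.
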