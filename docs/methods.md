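# Methods

## Problem and model

Missense variants in the Sanfilippo-syndrome (MPS III) genes — above all
*NAGLU* — are mostly catalogued as variants of uncertain significance
(VUS), and genome-wide pathogenicity predictors disagree with each other on
them. The package implements a gene-specific alternative: treat each
variant's vector of in-silico predictor scores

> Grantham distance, Sneath index, SIFT, PolyPhen-2, CADD, REVEL, MetaLR,
> MutationAssessor

as a draw from a two-component multivariate Gaussian mixture and learn the
two clusters *unsupervised*, from the VUS pool alone. One cluster is
interpreted as benign-like score profiles, the other as pathogenic-like;
labelled benign/pathogenic variants are used only afterwards, to validate
the clustering as a classifier.

For variant *i* with score vector `x_i ∈ R^p`:

    x_i | z_i = k ~ N(mu_k, Sigma_k),   P(z_i = k) = omega_k,  k in {1, 2}

with conjugate priors

    (omega_1, omega_2) ~ Dirichlet(1, 1)
    mu_k               ~ N(eta, tau)
    Sigma_k            ~ Inverse-Wishart(nu, Psi)

The data-driven defaults are `eta` = sample mean vector, `tau` = 10 × the
sample covariance (a deliberately wide prior on cluster means; a
`tau_scale` knob exposes the alternative reading of "scaled by 10" as
division), `nu = p`, `Psi` = the sample covariance. No standardization is
applied: the mixture is fitted on raw score scales, so CADD (range 0–32)
carries more deviance than the unit-interval scores — a property the DIC
elimination step inherits (below).

Posterior inference is by Gibbs sampling over the full conditionals:
assignments (categorical, responsibilities computed in log space), weights
(Dirichlet), means (Normal conjugate update with precision
`tau^-1 + n_k Sigma_k^-1`), covariances (inverse-Wishart with
`nu + n_k` degrees of freedom and scale `Psi + scatter_k`). An empty
cluster's mean/covariance are refreshed from the prior, which keeps the
chain proper without restarts; more than 50 consecutive empty sweeps
triggers a warning.

### Identifiability

Mixture likelihoods are invariant to relabelling. Draws are made
identifiable by enforcing `omega_1 < omega_2` in every retained draw
(swapping the whole parameter block when violated), under the modelling
assumption that the benign cluster is the *smaller* one. An exact tie is
broken by the mean of an anchor feature (REVEL by default, benign = lower);
the constraint in the strict form says nothing about ties, so the tie rule
is a package choice.

### Classification

For a new score vector, each retained draw m yields responsibilities
`p_{i,k,m}`; the per-draw label is `argmax_k p_{i,k,m}` and the final label
the mode over draws. The reported pathogenicity probability is the mean
over draws of the pathogenic responsibility; `>= 0.50` calls pathogenic.
A split vote is resolved to pathogenic and flagged — in a screening
context the sensitive call is the safer default. `sanfilippo_score` also
offers a `plug_in` mode that evaluates one responsibility at the
posterior-median parameters: a best-faith reconstruction of the
spreadsheet-calculator arithmetic built on the published centroid
percentiles, labelled as such because the calculator's exact mapping from
three percentiles per score to a probability is not documented.

### Model selection

DIC uses the observed-data mixture likelihood,
`D(theta) = -2 sum_i log sum_k omega_k N(x_i; mu_k, Sigma_k)`, with
Spiegelhalter's `p_D = Dbar - D(theta_bar)` and `theta_bar` the
element-wise posterior mean (weights renormalized, mean covariance
symmetrized and eigenvalue-clipped to SPD when needed). Backward
elimination refits the mixture on every leave-one-out subset, removes the
feature whose removal gives the lowest DIC if that improves on the current
model, and stops otherwise (or at one feature). Two caveats are recorded
in the trace rather than "corrected": (1) DIC across feature sets of
different dimension compares likelihoods on different scales — only the
within-step comparison (all subsets of equal size) is clean; (2) whether a
feature survives depends on its raw scale: a score whose within-cluster
density exceeds 1 (sub-unit scales like SIFT/REVEL) *raises* DIC when
removed, a unit-or-wider-scale noise feature lowers it. The synthetic
elimination benchmark is built accordingly: informative features at
sub-unit within-cluster scale, noise features at unit scale.

## Imputation

Missing score cells are completed by chained equations with predictive
mean matching: each incomplete column is regressed by OLS (with intercept)
on all other columns of the current completed matrix; a missing entry
receives the observed value of one of `n_donors = 5` donors with the
nearest fitted means (uniform draw; distance ties broken deterministically
by row index), over `n_cycles = 5` cycles, initialized at column means.
The donor property keeps every imputed value inside its column's empirical
support, which matters for the hard-bounded scores. Each data split
(training pool, validation, test) is imputed from its own observed values
only, so no information leaks from the unlabelled pool into evaluation.
One completed dataset feeds one mixture fit; `n_imputations > 1` returns a
list and leaves pooling to the caller.

## Synthetic data

The study's raw 612-variant table is not publicly deposited, so the
package ships a generator that emulates the *model*, not the data: a
two-component Gaussian mixture over the eight scores whose default
centroids and weights are the published posterior cluster estimates
(benign/pathogenic), clipped to the empirical score ranges of the study
table. The published table reports posterior SDs of the centroids
(standard-error scale), not within-cluster spread, so defaults use that SD
column scaled by `WITHIN_SD_SCALE = 5.0` — chosen once so the two
components sit ≈ 6 Mahalanobis units apart in 8 dimensions: clearly
separable overall while overlapping per feature, consistent with the
marginal spreads the study table reports. Covariances are diagonal by
default (within-cluster correlations are unknowable without the data);
full covariance matrices are accepted.

Range enforcement is by clipping (a documented bias; a truncated-sampling
switch exists). Clipping piles mass on a bound when a centroid hugs it —
most visibly SIFT's pathogenic centroid of 0.03 against the 0 bound, which
shifts the realized component mean to ≈ 0.076. That mirrors real SIFT
score pile-up at 0, but it means a Gaussian fit estimates the *clipped*
component mean, not the nominal centroid. Recovery checks therefore use
two estimands: centroid accuracy is assessed against nominal centroids in
within-SD units (clipping shifts are ≤ ~0.3 SD), while credible-interval
coverage is assessed against the analytic clipped-component means
(`component_clipped_means`), the quantity the fit actually targets.

The benchmark fixture reproduces the study design exactly: 415 unlabelled
VUS rows as the training pool, 101 benign + 96 pathogenic labelled rows
partitioned 99/98 into stratified validation and test sets (a class with
an odd count sends its extra record to validation first, alternating —
which is what yields 99/98 from 101 + 96). Missingness is MCAR and off by
default; it is injected explicitly where imputation is exercised, because
the study description both asserts complete training scores and describes
imputation.

What passing on synthetic data does *not* show: robustness to real
inter-predictor correlation structure, non-Gaussian score distributions,
label noise in clinical assertions, or informative missingness. The
synthetic results validate the machinery (conditionals, identifiability
handling, classification rule, metric panel), not the clinical claim.

## Evaluation

Pathogenic is the positive class. Sensitivity, specificity, accuracy,
balanced accuracy, PPV, NPV, Cohen's kappa (marginal expected agreement)
and F1 are computed from counts; metrics with zero denominators are NaN,
never 0. The no-information rate is the larger reference-class proportion;
accuracy is tested against it with the one-sided exact binomial test, and
gets an exact Clopper–Pearson interval from beta quantiles. ROC curves
sweep the distinct scores as thresholds with tied scores grouped, so the
trapezoidal AUC equals the tie-corrected Mann–Whitney concordance
probability (asserted against a brute-force pairwise estimator in tests).
Comparisons against published metric panels round half-up to 2 decimals,
matching the printed precision.

## Numerical choices

- All covariance work goes through Cholesky factorizations; sampled
  covariances are symmetrized; a singular sample covariance (constant
  column) is ridged by `1e-6 ×` its mean diagonal before use.
- Responsibilities and deviances are computed via log-sum-exp throughout;
  simultaneous density underflow cannot produce NaN.
- One `numpy` Generator per chain; assignment sampling consumes exactly
  one uniform variate per row in row order, making runs bit-reproducible
  under a seed. The pipeline fans a single global seed out to per-stage
  seeds by a stable 32-bit hash.
- Chain defaults are 20 000 sweeps, 5 000 burn-in, thinning 5 (3 000
  retained draws) — enough for stable 2.5/97.5 percentiles at 2-decimal
  reporting precision. Tests and the acceptance script use shorter chains
  (typically 1 500–2 000 sweeps, 500–600 burn-in) and study-scale problems
  (n = 415, p = 8; elimination at n = 300, p = 5, 20 replicates): the
  posterior for these well-separated problems mixes within a few dozen
  sweeps, and the package states these sizes as its benchmark choices.
- `K` is fixed at 2; configuration requesting anything else is rejected at
  validation.

## Known limitations

- The two-cluster Gaussian assumption is the model, not a finding; scores
  with atypical profiles (e.g. discordant conservation vs ensemble scores)
  get confident labels from whichever cluster is nearer.
- DIC across feature sets of different dimension is reported faithfully to
  the original procedure, caveat attached, rather than replaced by a
  dimension-invariant criterion.
- The plug-in scoring mode is a reconstruction of an undocumented
  spreadsheet calculation and can disagree with the draws-averaged
  probability near the decision boundary.
- Multiple imputation is supported mechanically (`n_imputations > 1`) but
  no Rubin's-rules pooling of downstream estimates is provided.
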