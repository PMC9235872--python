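# Methods

This note documents the models behind `oryzamix`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a user re-deriving results should know about.

## Hierarchical accession-mean model

Per site, replicate trait vectors are modelled as multivariate Student-t
around accession means, which are in turn normal around an intercept plus a
marker regression:

    y_i.      ~ t_nu( mu_acc[j(i)]. ; Sigma_e )
    mu_acc_j. ~ N_d( mu + u_j. Gamma ; Sigma_s )
    gamma_k.  ~ N_d( 0 ; Sigma_a )

- `nu = 3` by default: heavy tails give replicate outliers bounded
  influence. `nu` is configurable; as `nu` grows the fit converges to the
  Gaussian-error model.
- `u_j.` is row *j* of `U`, the eigenvectors of the van Raden relationship
  matrix scaled by square-root eigenvalues. With a Gaussian prior on the
  rows of `Gamma`, this principal-component regression is equivalent to a
  mixed model with genomic covariance `G` (multi-trait GBLUP).
- Priors: intercept `N(0, 1e6 I)` (effectively flat); Wishart priors with
  identity scale on the precision matrices, degrees of freedom 2 for the
  error and strain (residual genetic) covariances and 4 for the marker
  covariance — weakly informative, implying a roughly uniform prior on
  marker heritability. The Wishart scale matrices are configurable; the
  parameterisation (Wishart on precisions = inverse-Wishart on covariances)
  was chosen for conjugacy.

**Sampler.** Gibbs, with the Student-t written as a scale mixture of
normals (`w_i ~ Gamma(nu/2, nu/2)`). All conditionals are conjugate. Two
implementation points matter:

1. The supplied `U` is re-orthogonalised internally by SVD. The
   matrix-normal prior on `Gamma` (i.i.d. rows) is invariant to that right
   rotation, and orthogonal columns make `U'U` diagonal, so the `Gamma`
   update factorises into k independent d-dimensional draws instead of one
   (k·d)-dimensional solve.
2. Partially observed replicate vectors are imputed inside the sampler from
   the conditional multivariate normal given the observed traits (grouped
   by missingness pattern), keeping the multivariate likelihood
   well-defined.

Defaults: 2,000 burn-in, 4,000 sampling iterations, thinning 4, all seeds
explicit. Tests and the acceptance script pass shorter, explicitly sized
chains (hundreds of burn-in iterations) chosen for the small problems they
run; split-R-hat on the covariance diagonals is reported and warned about
above 1.1, so under-sampled runs are visible. Accession-mean point
estimates are the posterior means of the `mu_acc` draws — the conditional
posterior is unimodal, so this is a stable stand-in for the mode.

**Heritability.** Per posterior draw, with
`gebv_p = (U Gamma)'_p (U Gamma)_p / (N_acc - 1)`:

    marker_h2 = gebv / (gebv + Sigma_s_pp + Sigma_e_pp)
    broad_h2  = (gebv + Sigma_s_pp) / (gebv + Sigma_s_pp + Sigma_e_pp)

computed draw-wise and then summarised (posterior mean, central 95%
interval) — never as a ratio of posterior means. Note `Sigma_e` is the
*scale* matrix of the Student-t; with `nu = 3` the error variance is three
times the scale, so this is a scale-basis heritability (see the generator
section for why recovery tests compare on the same basis).

## VB Gaussian mixture with Dirichlet shrinkage

Accession means are clustered with a finite mixture, each group with its
own mean and full covariance, under the conjugate Dirichlet /
Normal-Wishart prior, fitted by coordinate-ascent variational inference.

Defaults and rationale:

- `alpha = 0.1` (Dirichlet concentration): small, so groups without support
  drain toward zero occupancy. The count of groups with at least two
  accessions at hard assignment ("non-empty groups") is one of the two
  group-number diagnostics; DIC is the other.
- Traits are standardised before fitting (flag-controlled): the
  zero-centred prior on group means presumes centred data, and
  standardisation makes the fitted partition invariant to per-trait affine
  rescaling.
- `lambda0 = 1` (prior mean-covariance scale), `nu0 = d + 2` (Wishart df),
  and Wishart scale `Sigma0 = I / nu0`, so the prior *expected precision*
  is the identity — matching the unit variance of standardised traits. A
  plain identity scale would put the prior expected precision at
  `nu0 * I`, i.e. prior component variances of `1/nu0`, which empirically
  drives the model toward many small, tight components and defeats the
  shrinkage; this default was changed accordingly and remains
  configurable.
- Convergence: relative ELBO change below 1e-8, required for 10
  consecutive sweeps (a single sub-tolerance step can be a lull while an
  unsupported component drains slowly), capped at 2,000 sweeps. The ELBO
  is asserted non-decreasing in tests.
- Initialisation: k-means++ with 10 restarts per VB start. Hard-assignment
  ties break toward the lowest group index.

**DIC.** `DIC = -2 * loglik(posterior means) + 2 * p_D` with
`p_D = 2 * (loglik(posterior means) - E_q[loglik])`, the expected
log-likelihood taken under the variational posterior (expectations of
`log pi` and of the Gaussian quadratic form, including the `d/beta`
mean-uncertainty term). `p_D >= 0` at a variational optimum up to
round-off. Lower is better.

A limitation worth knowing: `p_D` effectively counts
`d + d(d+1)/2 + 1` parameters per occupied component. At `d = 32` traits
and a few hundred accessions that penalty (~1,100 deviance units per
component) exceeds the deviance cost of merging two clusters at *any*
separation, because that cost grows only logarithmically with separation.
DIC comparisons at high trait dimension therefore favour merged solutions
whenever one is offered, and the group count should lean on the non-empty
count, stability across starts, and interpretability — which is how the
sweep is designed to be read.

**Multi-start and averaging.** `multi_start` runs independent fits from
distinct seeds and picks the lowest DIC; on well-separated data all starts
agree (DIC spread ~0). `average_runs` aligns group labels across runs to a
reference by Hungarian assignment on responsibility-column correlations and
averages the aligned responsibilities; a merge map (e.g. pooling two
intermediate groups) can be applied to the averaged probabilities.

**Group-number sweep.** `group_sweep` diversifies its starts: hard k-means,
softened k-means (one-hot blended 75% toward uniform, which lets
unsupported components drain early), and one explicitly collapsed start
(all mass on one component — the "no structure" candidate). Fits within 1%
relative DIC of the minimum are treated as statistically equivalent — the
same scale conventionally used to call fits from different starts
consistent — and the most parsimonious of them (fewest non-empty groups) is
reported. Without the collapsed candidate, the balanced two-way split of
genuinely unimodal data is a (near-)stable fixed point of the coordinate
ascent that k-means starts never escape, and the sweep would over-report
structure on a sizeable fraction of data realisations.

## Trait diagnostics

**Hotelling T² ranking.** One multivariate least-squares regression of the
bivariate response (first group's membership probability, pooled
intermediate-groups probability; the last group is redundant since
probabilities sum to one) on an intercept plus all standardised traits.
For trait *t* with coefficient pair `b_t` and covariance block
`V_t = (X'X)^-1_tt * Sigma_res`, the statistic is
`T2_t = b_t' V_t^-1 b_t / (n - q)` with `q` = traits + intercept. The
`1/(n - q)` normalisation keeps values on a unit-free scale; the *ranking*
is what is used downstream, and it is invariant to per-trait affine
rescaling. Rank-deficient designs fall back to a pseudoinverse with a
warning, as does a (near-)singular residual covariance (which occurs when
membership is perfectly predictable from the traits).

**Correlation switching.** Statistic per trait pair: the range (max − min)
of its within-group Pearson correlations — the simplest statistic that is
large exactly when a pair changes correlation across groups; alternative
statistics can be dropped in. The null permutes group labels (sizes
preserved); `p = (1 + #{null >= obs}) / (1 + B)` with `B = 9,999` by
default, so the smallest attainable p-value is 1e-4 and the 0.001
selection threshold is resolvable. Pairs with a constant trait inside a
group are skipped with a warning. Group-wise *variance* changes are not
separately tested: pairs with appreciable variance shifts are already
captured by the correlation and mean differences.

**Subsets.** `by_value` = traits with `T2 > 0.17`; `by_correlation` =
traits in pairs with switch `p <= 0.001`; `union` = their union. Both
thresholds are arguments. Subset re-fits run the mixture on the restricted
columns (default three a-priori groups, 20 starts) and report the adjusted
Rand index against the reference partition.

## Concordance

Cross-tabulations (counts and row percentages) of species × group and
subpopulation × group; unmatched accession IDs are reported, never silently
dropped. The uncertain designations *Oryza* spp. and *Oryza* hybr. are
pooled. Admixture partitioning labels accessions with *O. sativa* fraction
strictly above the threshold (default 0.5; 0.4 and 0.2 are the common
alternatives) as ADM/OSAT; missing fractions become "unknown". Core
selection requires agreement of species, phenotypic group, and
subpopulation under a configurable correspondence map (default:
P1 ↔ *O. rufipogon* ↔ {W1, W3, W6}; P4 ↔ *O. nivara* ↔ {W2, W5}) plus
admixture below 0.2; a `species_override` metadata column handles
re-classified accessions explicitly rather than by hard-coding. Sankey
links are exported as plain tables (source, target, count, accession list)
and are lossless per transition.

## Synthetic-data generator

The generator emulates the structure the pipeline assumes, with known
truth:

- Genotypes: per-SNP allele frequency uniform on [0.05, 0.95], dosages
  Binomial(2, p), monomorphic columns resampled. No linkage
  disequilibrium, demography, or genotyping error.
- Accession means: latent group ~ categorical (default weights
  106/43/73 — the relative sizes the package's default three-group setting
  targets); mean = group mean + polygenic deviation + within-group
  residual. Polygenic deviations are built *through the eigen-embedding of
  the simulated relationship matrix* with i.i.d. normal coefficients, so
  the hierarchical model's structural assumption holds exactly and
  parameter-recovery tests are meaningful.
- `heritability_target` is the marker heritability on the error-*scale*
  basis: the polygenic variance is set to
  `h/(1-h) * (mean within-group variance + error scale²)`. Because the
  model's heritability formula also uses the t scale parameter, fitted and
  generated values are comparable directly; the raw empirical variance
  ratio differs by the t inflation `nu/(nu-2)` and both versions are
  recorded in the truth dictionary.
- Replicate noise: multivariate t built as normal over a
  `sqrt(chi2(nu)/nu)` divisor shared across traits within a replicate
  (single error covariance); `nu = 3`, per-trait scale 1.0 by default.
  Observations masked completely at random (default 2%).
- Metadata: species label equals the latent group's species with
  probability `species_concordance` (default 0.7, the scale of agreement
  seen in curated wild-rice panels), otherwise uniform over the other
  labels; subpopulation drawn from the species' pool; admixture fraction
  Beta-distributed per group (low for the two species-like groups, centred
  near 0.5 for the intermediate group).
- Default group means, when not supplied, are drawn isotropically and
  scaled so the *minimum* pairwise distance is `group_separation * sqrt(d)`
  in pooled-SD units (≈ `group_separation` pooled SDs per trait
  coordinate, default 5) — well-separated by construction.

What passing tests on this generator do **not** show: robustness to
linkage structure, genotype–environment interaction, non-Gaussian trait
distributions within groups, informative missingness, or multi-site
imbalance. Those belong to real-data validation.

## Degenerate inputs and numerical details

- SNP filtering removes monomorphic sites and sites whose minor allele has
  at most one carrier; an all-filtered matrix raises. Missing dosages are
  mean-imputed per SNP before the relationship matrix is formed; allele
  frequencies are computed after filtering.
- Eigenvalues below `1e-8 x` the largest are treated as zero; `U` keeps
  only strictly positive directions, so `U U' = G` up to the discarded
  spectrum.
- Covariance draws guard symmetry explicitly; singular VB covariance
  updates retry with a relative ridge and warn.
- The mixture refuses `n_groups >= n_accessions`; the permutation test
  refuses fewer than two groups of at least three members.

## Problem sizes

Default test and acceptance problem sizes (a few hundred accessions, 5–32
traits, hundreds of SNPs, short explicit chains) were chosen so the full
cycle — generation, relationship matrix, Gibbs sampling, 20-start VB,
permutation tests — completes in tens of seconds on one CPU while leaving
the statistical properties (recovery correlations ≥ 0.95, heritability
calibration within ±0.1, shrinkage collapse, permutation calibration)
clearly resolvable.
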