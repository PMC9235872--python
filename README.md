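# oryzamix

Phenotype-driven stratification of wild-rice germplasm.

Genebank collections of the *Oryza rufipogon* species complex (ORSC) — the
wild progenitor gene pool of Asian rice, spanning perennial *O. rufipogon*,
annual *O. nivara*, and intermediate/admixed forms — carry species
designations that are often uncertain or inconsistent. `oryzamix` classifies
accessions from what can actually be measured: replicated phenotypes and SNP
genotypes. It is aimed at quantitative geneticists and genebank curators
working with structured germplasm panels, and every stage is equally usable
on synthetic data with known ground truth.

## What it computes

**1. Robust accession means (BLUE analogues).** Replicated measurements
`y_i.` (rows = replicates, columns = traits) from one site are fitted with a
multi-trait Bayesian hierarchical model

```
y_i.      ~ t_nu( mu_acc[j(i)]. ; Sigma_e )
mu_acc_j. ~ N_d( mu + u_j. Gamma ; Sigma_s )
gamma_k.  ~ N_d( 0 ; Sigma_a )
```

where `u_j.` is row *j* of the eigenvector embedding `U` (columns scaled by
square-root eigenvalues) of the van Raden genomic relationship matrix
`G = ZZ'/c`, so the marker regression is the Bayesian analogue of multi-trait
GBLUP. Student-t errors (`nu = 3`) damp outlying replicates. A Gibbs sampler
(scale-mixture representation) returns posterior accession means plus
per-trait marker heritability
`h2_M = gebv / (gebv + Sigma_s_pp + Sigma_e_pp)` with
`gebv = (U Gamma)'_p (U Gamma)_p / (N_acc - 1)`, and broad-sense
heritability `(gebv + Sigma_s_pp) / (gebv + Sigma_s_pp + Sigma_e_pp)`,
summarised per posterior draw.

**2. Phenotypic groups.** The accession-mean matrix is clustered with a
Bayesian Gaussian mixture (separate mean and covariance per group) fitted by
coordinate-ascent variational Bayes. A small Dirichlet concentration
(`alpha = 0.1`) shrinks unsupported groups to zero occupancy; model fit is
compared by a deviance information criterion (DIC), with multi-start runs
aligned by Hungarian matching and their membership probabilities averaged.
A sweep over the a-priori group number reports, per N_G, the best DIC and
the number of groups holding at least two accessions.

**3. Trait diagnostics.** Traits are ranked by a Hotelling T² statistic from
a multivariate regression of group-membership probabilities on all traits;
within-group trait correlations are compared across groups with a
permutation test (statistic: across-group range of the pairwise
correlation); trait subsets are selected by T² threshold, by correlation
switching, and their union, then used to re-fit the mixture and score
agreement (adjusted Rand index) with the full-data partition.

**4. Concordance.** Species designations, phenotypic groups, and genotypic
subpopulations (W1–W6) are cross-tabulated; accessions with *O. sativa*
admixture fraction above 0.5 are set aside as ADM/OSAT; "core" accessions —
those on which all three classifications agree and admixture is below 0.2 —
are listed; Sankey link tables track each accession across classifications.

## Worked example

```python
from oryzamix import (SimulationConfig, simulate_dataset, fit_hierarchical,
                      heritability, multi_start, average_runs, MixturePriors,
                      hotelling_rank, SamplerSettings)
from sklearn.metrics import adjusted_rand_score

cfg = SimulationConfig(n_accessions=120, n_snps=300, n_traits=8,
                       n_groups_true=3, replicate_count=3, seed=11)
sim = simulate_dataset(cfg)

fit = fit_hierarchical(sim.observations, embedding=sim.truth["embedding"],
                       sampler=SamplerSettings(n_burnin=1000, n_iter=2000,
                                               thin=2, seed=1))
her = heritability(fit)
print(her.table["broad_h2"].head(3).round(2))

fits, best = multi_start(fit.M, n_groups=4, priors=MixturePriors(alpha=0.1),
                         n_starts=20, seed=2)
avg = average_runs(fits, reference=best)
print("non-empty groups:", best.n_nonempty)
print("ARI:", round(adjusted_rand_score(sim.true_groups.to_numpy(),
                                        avg.hard_labels), 3))
print(hotelling_rank(fit.M, avg).head(3).round(3))
```

prints

```
trait
T00    0.99
T01    0.96
T02    0.99
Name: broad_h2, dtype: float64
non-empty groups: 3
ARI: 1.0
T00    0.564
T03    0.263
T05    0.207
Name: t2, dtype: float64
```

Three groups were simulated; fitting four a-priori groups leaves exactly
three non-empty (the Dirichlet prior empties the spare one) and the averaged
hard assignment reproduces the simulated partition exactly (adjusted Rand
index 1.0). Broad-sense heritabilities are near 1 here because the strong
between-group mean differences count as genetic variance. The T² ranking
identifies which traits best track the membership probabilities.

The same pipeline runs from the shell:

```bash
oryzamix simulate --n-accessions 120 --n-traits 8 --seed 11 --out data/
oryzamix relationship --genotypes data/genotypes.tsv --out data/
oryzamix fit-means --observations data/observations.csv \
    --embedding-g data/relationship_G.tsv --embedding-u data/relationship_U.tsv \
    --out run/
oryzamix fit-mixture --means run/accession_means.csv --n-groups 4 --out run/
oryzamix run-all --out full_run/     # everything, simulation included
```

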