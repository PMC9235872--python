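"""Synthetic wild-rice phenotype/genotype generator with known ground truth.

Emulates the structure of a germplasm phenotyping study: accessions fall into
a small number of latent phenotypic groups (mixture of Gaussians over trait
means with per-group covariances), carry polygenic trait deviations
structured by a SNP-derived relationship matrix with controllable
heritability, and are measured in replicate with heavy-tailed (multivariate
Student-t) noise and missing observations. Species labels agree with the
latent group with a configurable concordance, mimicking imperfect taxonomic
designations in genebank records.

Every downstream stage of the package is testable against the truth recorded
in the returned :class:`SyntheticDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relationship import filter_non_singleton, van_raden

__all__ = ["SimulationConfig", "SyntheticDataset",
           "simulate_genotypes", "simulate_means_and_observations",
           "simulate_dataset"]

#: genebank species designations cycled over latent groups
SPECIES_NAMES = ("O. rufipogon", "Oryza spp.", "O. nivara")

#: genotypic subpopulation pools observed to co-segregate with each species
SUBPOP_POOLS = (("W1", "W3", "W6"), ("ADM/OSAT",), ("W2", "W5"))

#: per-group Beta(a, b) parameters for the O. sativa admixture fraction:
#: low for the two "pure" species groups, centred near 0.5 for the
#: intermediate/admixed group
ADMIXTURE_BETA = ((1.0, 9.0), (3.0, 3.0), (1.0, 9.0))


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the screenhouse design the package targets: 222
    accessions, 32 quantitative traits, three latent phenotypic groups with
    weights proportional to the observed group sizes (106/43/73), two
    replicate plants per accession, Student-t replicate noise with 3 degrees
    of freedom, and moderate-to-high heritability.
    """

    n_accessions: int = 222
    n_snps: int = 1000
    n_traits: int = 32
    n_groups_true: int = 3
    group_weights: np.ndarray | None = None          # default: (106,43,73)/222
    group_means: np.ndarray | None = None            # default: generated
    group_separation: float = 5.0                    # pooled-SD units, used
                                                     # when group_means is None
    group_covariances: list | None = None            # default: identity each
    heritability_target: float | np.ndarray = 0.6    # marker h2, scale basis
    error_scale: float | np.ndarray = 1.0            # Student-t scale, per trait
    replicate_count: int = 2
    error_df: float = 3.0
    missing_rate: float = 0.02
    species_concordance: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_accessions < 2 or self.n_snps < 2:
            raise ConfigurationError("need >= 2 accessions and >= 2 SNPs")
        if self.n_traits < 1 or self.n_groups_true < 1:
            raise ConfigurationError("need >= 1 trait and >= 1 group")
        if self.replicate_count < 1:
            raise ConfigurationError("replicate_count must be >= 1")
        if self.error_df <= 0:
            raise ConfigurationError("error_df must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.species_concordance <= 1.0:
            raise ConfigurationError("species_concordance must be in [0, 1]")

        if self.group_weights is None:
            base = np.array([106.0, 43.0, 73.0])
            if self.n_groups_true == 3:
                w = base
            else:
                w = np.ones(self.n_groups_true)
            self.group_weights = w / w.sum()
        else:
            self.group_weights = np.asarray(self.group_weights, dtype=float)
            if self.group_weights.shape != (self.n_groups_true,):
                raise ConfigurationError("group_weights length mismatch")
            if np.any(self.group_weights < 0) or not np.isclose(
                    self.group_weights.sum(), 1.0):
                raise ConfigurationError("group_weights must sum to 1")

        if self.group_covariances is None:
            self.group_covariances = [np.eye(self.n_traits)
                                      for _ in range(self.n_groups_true)]
        else:
            self.group_covariances = [np.asarray(S, dtype=float)
                                      for S in self.group_covariances]
            if len(self.group_covariances) != self.n_groups_true:
                raise ConfigurationError("one covariance per group required")
            for S in self.group_covariances:
                if S.shape != (self.n_traits, self.n_traits):
                    raise ConfigurationError("covariance dimension mismatch")
                if not np.allclose(S, S.T):
                    raise ConfigurationError("covariance not symmetric")
                if np.linalg.eigvalsh(S).min() <= 0:
                    raise ConfigurationError("covariance not positive definite")

        if self.group_means is not None:
            self.group_means = np.asarray(self.group_means, dtype=float)
            if self.group_means.shape != (self.n_groups_true, self.n_traits):
                raise ConfigurationError("group_means shape mismatch")

        h = np.broadcast_to(np.asarray(self.heritability_target, float),
                            (self.n_traits,)).copy()
        if np.any(h < 0) or np.any(h > 1):
            raise ConfigurationError("heritability_target must be in [0, 1]")
        if np.any(h == 1.0):
            raise ConfigurationError(
                "heritability_target == 1 is degenerate (requires zero "
                "residual and error variance)")
        self.heritability_target = h
        self.error_scale = np.broadcast_to(
            np.asarray(self.error_scale, float), (self.n_traits,)).copy()
        if np.any(self.error_scale < 0):
            raise ConfigurationError("error_scale must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated data plus the ground truth behind it."""

    genotypes: np.ndarray                 # accession x SNP dosages {0,1,2}
    observations: pd.DataFrame            # long: accession_id, site, trait,
                                          # replicate, value
    true_groups: pd.Series                # accession_id -> int group label
    true_accession_means: pd.DataFrame    # accession x trait
    metadata: pd.DataFrame                # species, subpopulation, admixture
    accession_ids: list
    trait_names: list
    truth: dict = field(default_factory=dict)   # generative scales and
                                                # realized heritabilities


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw an accession x SNP dosage matrix with no monomorphic column.

    Each SNP gets an allele frequency uniform on [0.05, 0.95]; dosages are
    Binomial(2, p). Columns that come out monomorphic are resampled.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_accessions, config.n_snps
    geno = np.empty((n, m), dtype=np.int64)
    freqs = rng.uniform(0.05, 0.95, size=m)
    for s in range(m):
        for _ in range(1000):
            col = rng.binomial(2, freqs[s], size=n)
            if col.min() != col.max():
                break
            freqs[s] = rng.uniform(0.05, 0.95)
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError("could not draw a polymorphic SNP")
        geno[:, s] = col
    return geno


def _default_group_means(config: SimulationConfig, pooled_sd: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Random group means with a prescribed minimum pairwise separation.

    Directions are drawn isotropically, centred, scaled per trait by the
    pooled within-group SD, then rescaled so the smallest pairwise distance
    in pooled-SD units equals ``group_separation * sqrt(n_traits)`` (i.e.
    roughly ``group_separation`` pooled SDs per trait coordinate).
    """
    M, d = config.n_groups_true, config.n_traits
    if M == 1:
        return np.zeros((1, d))
    raw = rng.standard_normal((M, d))
    raw -= raw.mean(axis=0)
    scaled = raw / pooled_sd  # distances in SD units
    dmin = np.inf
    for a in range(M):
        for b in range(a + 1, M):
            dmin = min(dmin, np.linalg.norm(scaled[a] - scaled[b]))
    if dmin <= 0:
        raise ConfigurationError("degenerate random group means")
    factor = config.group_separation * np.sqrt(d) / dmin
    return raw * factor


def simulate_means_and_observations(
        config: SimulationConfig,
        genotypes: np.ndarray,
        rng: np.random.Generator | None = None) -> SyntheticDataset:
    """Generate latent groups, accession means, replicates and metadata.

    The accession mean decomposes as

        mean = group mean + polygenic deviation + within-group residual

    where the polygenic deviation lives in the column space of the
    eigen-embedding of the relationship matrix built from ``genotypes``
    (coefficients i.i.d. normal), scaled so that the per-trait marker
    heritability on the error-scale basis equals ``heritability_target``.
    Replicates add multivariate-t noise (normal over a shared
    sqrt(chi2/df)); observations are masked completely at random.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, d, M = config.n_accessions, config.n_traits, config.n_groups_true
    if genotypes.shape[0] != n:
        raise ConfigurationError("genotypes row count != n_accessions")

    acc_ids = [f"ACC{i:04d}" for i in range(n)]
    traits = [f"T{p:02d}" for p in range(d)]

    filtered, _ = filter_non_singleton(genotypes)
    emb = van_raden(filtered, accession_ids=acc_ids)

    # variance components (error-scale basis)
    sigma_s2 = np.mean([np.diag(S) for S in config.group_covariances], axis=0)
    sigma_e2 = config.error_scale ** 2
    h = config.heritability_target
    sigma_g2 = h / (1.0 - h) * (sigma_s2 + sigma_e2)

    pooled_sd = np.sqrt(sigma_s2 + sigma_g2)
    group_means = (config.group_means if config.group_means is not None
                   else _default_group_means(config, pooled_sd, rng))

    z = rng.choice(M, size=n, p=config.group_weights)

    # polygenic deviations through the eigen-embedding; empirical variance of
    # (U c)_j over accessions is sigma_a^2 * tr(G)/n, so scale accordingly
    U = emb.U
    trG_n = np.trace(emb.G) / n
    sigma_a = np.sqrt(sigma_g2 / max(trG_n, 1e-12))
    coefs = rng.standard_normal((U.shape[1], d)) * sigma_a
    polygenic = U @ coefs

    residual = np.empty((n, d))
    chols = [np.linalg.cholesky(S) for S in config.group_covariances]
    for m in range(M):
        idx = np.flatnonzero(z == m)
        residual[idx] = rng.standard_normal((idx.size, d)) @ chols[m].T

    means = group_means[z] + polygenic + residual

    # replicate observations with shared-scale multivariate t noise
    R = config.replicate_count
    gam = rng.chisquare(config.error_df, size=(n, R)) / config.error_df
    noise = (rng.standard_normal((n, R, d)) * config.error_scale
             / np.sqrt(gam)[:, :, None])
    obs = means[:, None, :] + noise
    mask = rng.random((n, R, d)) < config.missing_rate
    obs_masked = np.where(mask, np.nan, obs)

    rows = pd.DataFrame({
        "accession_id": np.repeat(acc_ids, R * d),
        "site": "SYN",
        "trait": np.tile(traits, n * R),
        "replicate": np.tile(np.repeat(np.arange(1, R + 1), d), n),
        "value": obs_masked.reshape(-1),
    })
    observations = rows.dropna(subset=["value"]).reset_index(drop=True)

    # metadata: species / subpopulation concordant with latent group with
    # probability species_concordance, otherwise uniform over other labels
    species = np.empty(n, dtype=object)
    subpop = np.empty(n, dtype=object)
    admix = np.empty(n)
    for j in range(n):
        g = z[j]
        if rng.random() < config.species_concordance:
            lab = g % len(SPECIES_NAMES)
        else:
            others = [k for k in range(len(SPECIES_NAMES))
                      if k != g % len(SPECIES_NAMES)]
            lab = others[rng.integers(len(others))]
        species[j] = SPECIES_NAMES[lab]
        pool = SUBPOP_POOLS[lab]
        subpop[j] = pool[rng.integers(len(pool))]
        a, b = ADMIXTURE_BETA[g % len(ADMIXTURE_BETA)]
        admix[j] = rng.beta(a, b)
    metadata = pd.DataFrame({
        "accession_id": acc_ids,
        "species": species,
        "subpopulation": subpop,
        "osat_admixture_fraction": admix,
        "site": "SYN",
    })

    var_means = means.var(axis=0, ddof=1)
    t_var_factor = (config.error_df / (config.error_df - 2)
                    if config.error_df > 2 else np.inf)
    truth = {
        "sigma_g2": sigma_g2,
        "sigma_s2": sigma_s2,
        "error_scale2": sigma_e2,
        "group_means": group_means,
        "realized_broad_h2_scale": var_means / (var_means + sigma_e2),
        "realized_broad_h2_empirical":
            var_means / (var_means + sigma_e2 * t_var_factor),
        "embedding": emb,
    }

    return SyntheticDataset(
        genotypes=np.asarray(genotypes),
        observations=observations,
        true_groups=pd.Series(z, index=acc_ids, name="group"),
        true_accession_means=pd.DataFrame(means, index=acc_ids,
                                          columns=traits),
        metadata=metadata,
        accession_ids=acc_ids,
        trait_names=traits,
        truth=truth,
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Convenience wrapper: genotypes then means/observations, one seed."""
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config, rng)
    return simulate_means_and_observations(config, geno, rng)
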