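"""Genomic relationship matrix and its eigenvector embedding.

The marker information enters the accession-mean model through the van Raden
genomic relationship matrix ``G = Z Z' / c`` built from biallelic SNP dosages,
where ``Z`` is the column-centred dosage matrix and ``c = 2 * sum(p(1-p))``.
Downstream regression uses the eigenvectors of ``G`` scaled by the square
roots of their eigenvalues, so that ``U U' = G`` and the columns of ``U`` are
orthogonal; a Gaussian prior on the regression coefficients then makes the
fit equivalent to a mixed model with covariance ``G``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RelationshipEmbedding",
    "EmptyMarkerError",
    "DegenerateInputError",
    "filter_non_singleton",
    "van_raden",
]


class EmptyMarkerError(ValueError):
    """Raised when marker filtering removes every SNP."""


class DegenerateInputError(ValueError):
    """Raised when the genotype matrix carries no usable variation."""


@dataclass
class RelationshipEmbedding:
    """Relationship matrix ``G`` with its scaled-eigenvector embedding ``U``.

    Attributes
    ----------
    G : (n, n) ndarray
        Symmetric van Raden relationship matrix.
    U : (n, k) ndarray
        Eigenvectors of ``G`` for strictly positive eigenvalues, each column
        multiplied by the square root of its eigenvalue, so ``U @ U.T == G``
        up to the discarded (numerically zero) spectrum.
    eigenvalues : (k,) ndarray
        The retained eigenvalues, descending, all positive.
    kept_snp_count : int
        Number of SNPs that went into ``G``.
    accession_ids : list of str or None
        Row labels, if known.
    """

    G: np.ndarray
    U: np.ndarray
    eigenvalues: np.ndarray
    kept_snp_count: int
    accession_ids: list | None = field(default=None)

    @property
    def n_accessions(self) -> int:
        return self.G.shape[0]


def _as_dosage(genotypes) -> np.ndarray:
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (accessions x SNPs)")
    valid = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
    if not valid.all():
        raise ValueError("genotypes must be dosages in {0,1,2} or NaN")
    return g


def filter_non_singleton(genotypes) -> tuple[np.ndarray, int]:
    """Drop monomorphic SNPs and SNPs whose minor allele has <= 1 carrier.

    A carrier is an accession holding at least one copy of the minor allele
    (dosage >= 1 for the alternate allele, <= 1 for the reference allele,
    whichever is minor by frequency). Missing genotypes are ignored when
    counting.

    Returns
    -------
    (filtered, kept_count)

    Raises
    ------
    EmptyMarkerError
        If no SNP survives.
    """
    g = _as_dosage(genotypes)
    n, m = g.shape
    keep = np.zeros(m, dtype=bool)
    for s in range(m):
        col = g[:, s]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        p_alt = obs.mean() / 2.0
        if p_alt == 0.0 or p_alt == 1.0:
            continue  # monomorphic
        if p_alt <= 0.5:
            carriers = int(np.sum(obs >= 1))
        else:
            carriers = int(np.sum(obs <= 1))
        keep[s] = carriers >= 2
    if not keep.any():
        raise EmptyMarkerError("all SNPs are monomorphic or singletons")
    return g[:, keep], int(keep.sum())


def van_raden(genotypes, eig_rel_tol: float = 1e-8,
              accession_ids=None) -> RelationshipEmbedding:
    """Build the van Raden relationship matrix and its eigen-embedding.

    Missing dosages are mean-imputed per SNP before centring. Allele
    frequencies ``p`` are estimated from the supplied (already filtered)
    matrix. Eigenvalues below ``eig_rel_tol`` times the largest are treated
    as zero and their eigenvectors dropped from ``U``.

    Parameters
    ----------
    genotypes : (n, m) array of {0,1,2} dosages, NaN for missing.
    eig_rel_tol : float
        Relative threshold defining a "non-zero" eigenvalue.
    accession_ids : sequence of str, optional
        Row labels stored on the result.

    Raises
    ------
    DegenerateInputError
        If the matrix has no polymorphism (``c == 0``) or zero rank.
    """
    g = _as_dosage(genotypes)
    n, m = g.shape
    if n < 2 or m < 2:
        raise DegenerateInputError("need at least 2 accessions and 2 SNPs")
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean, g)
    p_hat = g.mean(axis=0) / 2.0
    c = 2.0 * np.sum(p_hat * (1.0 - p_hat))
    if c <= 0.0:
        raise DegenerateInputError("no polymorphic SNPs (normaliser c = 0)")
    Z = g - 2.0 * p_hat
    G = (Z @ Z.T) / c
    G = 0.5 * (G + G.T)  # enforce exact symmetry

    evals, evecs = np.linalg.eigh(G)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0.0:
        raise DegenerateInputError("relationship matrix has rank 0")
    kept = evals > eig_rel_tol * evals[0]
    evals = evals[kept]
    U = evecs[:, kept] * np.sqrt(evals)

    ids = list(accession_ids) if accession_ids is not None else None
    return RelationshipEmbedding(G=G, U=U, eigenvalues=evals,
                                 kept_snp_count=m, accession_ids=ids)
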