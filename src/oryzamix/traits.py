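"""Trait diagnostics: Hotelling T² ranking, within-group correlations,
correlation-switch permutation tests, and trait-subset selection/refits.

The ranking regresses the (bivariate) group-membership probabilities — the
first group plus the pooled intermediate groups; the last group is redundant
because probabilities sum to one — on all standardised traits jointly. Each
trait's pair of coefficients, whitened by its estimated covariance block and
scaled by the residual degrees of freedom, gives a Hotelling T² measure of
how strongly the trait's values track group membership. The statistic is
used for *ranking*, not significance testing.

Correlation switching asks whether a trait pair's within-group Pearson
correlation varies across groups more than expected by chance; the statistic
is the across-group range (max - min) of the correlation and the null is
built by permuting group labels (group sizes preserved).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .mixture import (AveragedAssignment, MixturePriors, average_runs,
                      multi_start)

__all__ = [
    "TraitDiagnostics", "hotelling_rank", "group_correlations",
    "correlation_switch_test", "select_subsets", "refit_with_subset",
]


@dataclass
class TraitDiagnostics:
    t2: pd.Series
    group_correlations: dict
    switch_pvalues: pd.DataFrame
    subsets: dict


def _response_matrix(assignment, response_groups) -> np.ndarray:
    if isinstance(assignment, AveragedAssignment):
        R = assignment.mean_responsibilities
    else:
        R = np.asarray(assignment, float)
    if R.shape[1] < 3:
        raise ValueError("need >= 3 groups for the bivariate response")
    if response_groups is None:
        response_groups = ((0,), tuple(range(1, R.shape[1] - 1)))
    cols = [R[:, list(g)].sum(axis=1) for g in response_groups]
    return np.stack(cols, axis=1)


def hotelling_rank(means, assignment,
                   response_groups=None) -> pd.Series:
    """Rank traits by Hotelling T² against group-membership probabilities.

    Parameters
    ----------
    means : DataFrame or array, accessions x traits.
    assignment : AveragedAssignment or responsibility matrix with >= 3
        groups; the response is (first group, pooled middle groups) by
        default, or as given by ``response_groups`` (tuples of column
        indices to sum).

    Returns
    -------
    Series of T² values sorted descending, indexed by trait.

    Notes
    -----
    One joint least-squares regression with intercept on standardised
    traits; for trait t with coefficient 2-vector ``b_t`` and covariance
    block ``V_t = (X'X)^-1_tt * Sigma_res``,
    ``T²_t = b_t' V_t^-1 b_t / (n - q)``. Rank-deficient designs fall back
    to the pseudoinverse with a warning.
    """
    X = means.to_numpy(float) if isinstance(means, pd.DataFrame) \
        else np.asarray(means, float)
    names = (list(means.columns) if isinstance(means, pd.DataFrame)
             else [f"T{p:02d}" for p in range(X.shape[1])])
    Y = _response_matrix(assignment, response_groups)
    n, d = X.shape
    q = d + 1
    if n <= q:
        raise ValueError(f"need n > {q} accessions for {d} traits")
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    D = np.column_stack([np.ones(n), Xs])
    XtX = D.T @ D
    rank = np.linalg.matrix_rank(XtX)
    if rank < q:
        warnings.warn("collinear predictors; using pseudoinverse",
                      RuntimeWarning)
        XtX_inv = np.linalg.pinv(XtX)
    else:
        XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (D.T @ Y)
    E = Y - D @ B
    Sigma_res = (E.T @ E) / (n - q)
    # guard against a (near-)singular residual covariance, which arises when
    # membership probabilities are perfectly predicted by the traits
    if np.linalg.cond(Sigma_res) > 1e12:
        warnings.warn("residual covariance nearly singular; using "
                      "pseudoinverse for T²", RuntimeWarning)
        solve = lambda V, b: np.linalg.pinv(V) @ b  # noqa: E731
    else:
        solve = np.linalg.solve
    t2 = np.empty(d)
    for t in range(d):
        b = B[t + 1]
        V = XtX_inv[t + 1, t + 1] * Sigma_res
        t2[t] = float(b @ solve(V, b)) / (n - q)
    return pd.Series(t2, index=names, name="t2").sort_values(ascending=False)


def group_correlations(means, hard_labels, min_size: int = 3) -> dict:
    """Within-group Pearson correlation matrices.

    Groups with fewer than ``min_size`` members are excluded with a warning.
    Pairwise-complete observations are used when values are missing.
    """
    df = means if isinstance(means, pd.DataFrame) \
        else pd.DataFrame(np.asarray(means, float))
    labels = np.asarray(hard_labels)
    out = {}
    for g in np.unique(labels):
        sub = df.loc[labels == g]
        if len(sub) < min_size:
            warnings.warn(f"group {g} has {len(sub)} members (< {min_size}); "
                          "excluded from correlation analysis", RuntimeWarning)
            continue
        out[g] = sub.corr()
    return out


def _group_corr_stack(X: np.ndarray, labels: np.ndarray,
                      groups: list) -> np.ndarray:
    """(n_groups, d, d) stack of within-group correlation matrices."""
    mats = []
    for g in groups:
        sub = X[labels == g]
        with np.errstate(invalid="ignore", divide="ignore"):
            mats.append(np.corrcoef(sub.T))
    return np.stack(mats)


def correlation_switch_test(means, hard_labels, n_permutations: int = 9999,
                            seed: int = 0, min_size: int = 3) -> pd.DataFrame:
    """Permutation test for across-group correlation heterogeneity.

    Observed statistic per trait pair: range (max - min) of its within-group
    correlations. The null permutes accession group labels (sizes
    preserved); ``p = (1 + #{null >= observed}) / (1 + B)``, so p-values lie
    in [1/(B+1), 1] and are never exactly zero.

    Pairs involving a trait that is constant within some group are skipped
    with a warning (their correlation is undefined).

    Returns
    -------
    DataFrame with columns trait_a, trait_b, observed_range, p_value.
    """
    df = means if isinstance(means, pd.DataFrame) \
        else pd.DataFrame(np.asarray(means, float))
    X = df.to_numpy(float)
    names = list(df.columns)
    labels = np.asarray(hard_labels)
    sizes = pd.Series(labels).value_counts()
    groups = [g for g in sizes.index if sizes[g] >= min_size]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with enough members")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    d = X.shape[1]
    iu = np.triu_indices(d, k=1)

    obs_stack = _group_corr_stack(X, labels, groups)
    bad = np.isnan(obs_stack).any(axis=0)[iu]
    if bad.any():
        warnings.warn(f"{int(bad.sum())} trait pairs skipped (constant "
                      "trait within a group)", RuntimeWarning)
    obs_range = (obs_stack.max(axis=0) - obs_stack.min(axis=0))[iu]

    exceed = np.zeros(len(obs_range))
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        st = _group_corr_stack(X, perm, groups)
        with np.errstate(invalid="ignore"):
            rng_null = (np.nanmax(st, axis=0) - np.nanmin(st, axis=0))[iu]
        exceed += rng_null >= obs_range
    pvals = (1.0 + exceed) / (1.0 + n_permutations)

    rows = []
    for idx, (a, b) in enumerate(zip(*iu)):
        if bad[idx]:
            continue
        rows.append({"trait_a": names[a], "trait_b": names[b],
                     "observed_range": obs_range[idx],
                     "p_value": pvals[idx]})
    return pd.DataFrame(rows)


def select_subsets(t2: pd.Series, switch_pvalues: pd.DataFrame,
                   t2_threshold: float = 0.17,
                   p_threshold: float = 0.001) -> dict:
    """Trait subsets by value, by correlation switching, and their union.

    by_value: traits with T² > ``t2_threshold``. by_correlation: every trait
    appearing in a pair whose switch p-value is <= ``p_threshold``. union:
    their set union. Empty subsets warn rather than fail.
    """
    by_value = [t for t, v in t2.items() if v > t2_threshold]
    sig = switch_pvalues[switch_pvalues["p_value"] <= p_threshold]
    by_corr = sorted(set(sig["trait_a"]) | set(sig["trait_b"]),
                     key=list(t2.index).index)
    union = sorted(set(by_value) | set(by_corr), key=list(t2.index).index)
    for name, subset in (("by_value", by_value),
                         ("by_correlation", by_corr)):
        if not subset:
            warnings.warn(f"subset {name} is empty at the given thresholds",
                          RuntimeWarning)
    return {"by_value": by_value, "by_correlation": by_corr, "union": union}


def refit_with_subset(means: pd.DataFrame, trait_subset,
                      reference_labels, n_groups: int = 3,
                      n_starts: int = 20,
                      priors: MixturePriors | None = None,
                      seed: int = 0) -> tuple[AveragedAssignment, float]:
    """Re-fit the mixture on a trait subset; score agreement with a
    reference partition by adjusted Rand index.

    ``reference_labels`` is typically the full-data merged (e.g. three-way)
    partition.
    """
    subset = list(trait_subset)
    if not subset:
        raise ValueError("trait subset is empty")
    sub = means[subset]
    fits, best = multi_start(sub, n_groups, priors, n_starts=n_starts,
                             seed=seed)
    avg = average_runs(fits, reference=best)
    ari = adjusted_rand_score(np.asarray(reference_labels), avg.hard_labels)
    return avg, float(ari)


def full_diagnostics(means: pd.DataFrame, assignment: AveragedAssignment,
                     n_permutations: int = 9999, seed: int = 0,
                     t2_threshold: float = 0.17,
                     p_threshold: float = 0.001,
                     merged_labels=None) -> TraitDiagnostics:
    """Convenience wrapper running the whole trait-diagnostic stage."""
    labels = (merged_labels if merged_labels is not None
              else assignment.hard_labels)
    t2 = hotelling_rank(means, assignment)
    gcorr = group_correlations(means, labels)
    pvals = correlation_switch_test(means, labels,
                                    n_permutations=n_permutations, seed=seed)
    subsets = select_subsets(t2, pvals, t2_threshold, p_threshold)
    return TraitDiagnostics(t2=t2, group_correlations=gcorr,
                            switch_pvalues=pvals, subsets=subsets)
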