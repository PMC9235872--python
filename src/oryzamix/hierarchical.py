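"""Multi-trait Bayesian hierarchical accession-mean model with robust errors.

Replicated phenotype observations (one site at a time) are modelled as

    y_i.      ~ t_nu( mu^acc_{j[i]}. ; Sigma_e )          (replicate rows)
    mu^acc_j. ~ N_d( mu + u_j. Gamma ; Sigma_s )          (accession means)
    gamma_k.  ~ N_d( 0 ; Sigma_a )                        (marker coefficients)

where ``u_j.`` is row j of the scaled eigenvector embedding of the genomic
relationship matrix, so the regression on markers is the Bayesian analogue of
a multi-trait mixed model (GBLUP). The Student-t error (df ``nu``, default 3)
dampens outlying replicates; it is handled as a scale mixture of normals.
The intercept has a flat N(0, 1e6 I) prior; covariances carry
weakly-informative Wishart priors on the precision scale (identity scale
matrix; df 2 for Sigma_e and Sigma_s, df 4 for Sigma_a).

Posterior summaries of the accession means (the posterior mean of their
draws, a stable stand-in for the mode of the unimodal conditional posterior)
play the role of BLUEs for all downstream analyses. Per-draw genome-estimated
breeding values (GEBV = U Gamma) yield marker and broad-sense heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relationship import RelationshipEmbedding

__all__ = [
    "HierarchicalPriors", "SamplerSettings", "AccessionMeans",
    "HeritabilityReport", "AlignmentError", "UndefinedHeritabilityError",
    "fit_hierarchical", "heritability",
]


class AlignmentError(ValueError):
    """Observation and embedding accession sets do not overlap correctly."""


class UndefinedHeritabilityError(ValueError):
    """Total phenotypic variance is zero; heritability undefined."""


@dataclass
class HierarchicalPriors:
    """Hyperparameters of the hierarchical model.

    ``wishart_df_*`` are prior degrees of freedom of the Wishart priors on
    the corresponding precision matrices (identity scale); equivalently
    inverse-Wishart on the covariances.
    """

    intercept_variance: float = 1e6
    error_df: float = 3.0
    wishart_df_error: float = 2.0
    wishart_df_strain: float = 2.0
    wishart_df_marker: float = 4.0

    def __post_init__(self):
        for name in ("intercept_variance", "error_df", "wishart_df_error",
                     "wishart_df_strain", "wishart_df_marker"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SamplerSettings:
    n_burnin: int = 2000
    n_iter: int = 4000
    thin: int = 4
    seed: int = 0


@dataclass
class AccessionMeans:
    """Posterior summaries from :func:`fit_hierarchical`."""

    M: pd.DataFrame                       # accession x trait posterior means
    intercept: pd.Series
    marker_coefficients: np.ndarray       # k x d posterior mean of Gamma
    Sigma_e: np.ndarray
    Sigma_s: np.ndarray
    Sigma_a: np.ndarray | None
    draws: dict                           # thinned chains used downstream
    diagnostics: dict                     # split-Rhat per covariance diagonal
    n_accessions: int
    traits: list
    accession_ids: list


@dataclass
class HeritabilityReport:
    """Per-trait GEBV variance and marker/broad-sense heritability.

    ``table`` has one row per trait with posterior means and 95% intervals;
    ``draws`` holds the per-draw values behind them.
    """

    table: pd.DataFrame
    draws: dict


def _split_rhat(chain: np.ndarray) -> float:
    """Split-R-hat of a single chain (split into two halves)."""
    n = len(chain) // 2
    if n < 2:
        return np.nan
    halves = np.asarray([chain[:n], chain[n:2 * n]], dtype=float)
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within <= 0:
        return np.nan
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def _prepare(observations: pd.DataFrame, traits=None):
    """Long observations -> (Y with NaN, accession index, ids, traits)."""
    req = {"accession_id", "trait", "replicate", "value"}
    missing_cols = req - set(observations.columns)
    if missing_cols:
        raise ValueError(f"observations missing columns {sorted(missing_cols)}")
    obs = observations
    if "site" in obs.columns and obs["site"].nunique() > 1:
        raise ValueError("multiple sites present: fit each site separately")
    if not np.isfinite(obs["value"].to_numpy(float)).all():
        raise ValueError("non-finite trait values present")
    dup = obs.duplicated(["accession_id", "trait", "replicate"])
    if dup.any():
        raise ValueError("duplicate (accession, trait, replicate) rows")
    wide = obs.pivot_table(index=["accession_id", "replicate"],
                           columns="trait", values="value", aggfunc="first")
    if traits is None:
        traits = sorted(wide.columns)
    wide = wide.reindex(columns=traits)
    acc_ids = wide.index.get_level_values(0)
    uniq = list(pd.unique(acc_ids))
    acc_map = {a: i for i, a in enumerate(uniq)}
    acc_idx = np.asarray([acc_map[a] for a in acc_ids])
    return wide.to_numpy(float), acc_idx, uniq, list(traits)


def fit_hierarchical(observations: pd.DataFrame,
                     embedding: RelationshipEmbedding | None = None,
                     priors: HierarchicalPriors | None = None,
                     sampler: SamplerSettings | None = None,
                     traits=None) -> AccessionMeans:
    """Gibbs sampler for the robust multi-trait hierarchical model.

    Parameters
    ----------
    observations : DataFrame
        Long format with columns accession_id, site, trait, replicate, value.
        Missing values may simply be absent rows; partially observed
        replicate vectors are imputed inside the sampler from the
        conditional multivariate normal.
    embedding : RelationshipEmbedding, optional
        Scaled eigenvector embedding of the relationship matrix. ``None``
        runs the no-marker model (Gamma fixed at zero, marker h2 = 0).
    priors, sampler : see :class:`HierarchicalPriors`,
        :class:`SamplerSettings`.
    traits : sequence, optional
        Trait order to use (default: sorted unique trait names).

    Returns
    -------
    AccessionMeans

    Raises
    ------
    AlignmentError
        If observation accessions are absent from the embedding.
    FloatingPointError
        If the sampler state goes non-finite (reported with the iteration).
    """
    priors = priors or HierarchicalPriors()
    sampler = sampler or SamplerSettings()
    rng = np.random.default_rng(sampler.seed)

    Y, acc_idx, acc_ids, traits = _prepare(observations, traits)
    N, d = Y.shape
    J = len(acc_ids)
    nu = priors.error_df

    if embedding is not None:
        if embedding.accession_ids is not None:
            emb_pos = {a: i for i, a in enumerate(embedding.accession_ids)}
            missing = [a for a in acc_ids if a not in emb_pos]
            if missing:
                raise AlignmentError(
                    f"{len(missing)} accessions absent from embedding, e.g. "
                    f"{missing[:3]}")
            Uraw = embedding.U[[emb_pos[a] for a in acc_ids]]
        else:
            if embedding.U.shape[0] != J:
                raise AlignmentError("embedding size != accession count and "
                                     "no accession_ids to align on")
            Uraw = embedding.U
        # re-orthogonalise so the Gamma update factorises over rows; the
        # i.i.d. row prior on Gamma is invariant to this rotation
        P, s, Vt = np.linalg.svd(Uraw, full_matrices=False)
        keep = s > 1e-10 * max(s[0], 1e-300)
        Uo = P[:, keep] * s[keep]
        s2 = s[keep] ** 2
        V = Vt[keep].T                  # k_raw x k, maps Gamma' -> Gamma
        k = Uo.shape[1]
    else:
        Uo = np.zeros((J, 0))
        s2 = np.zeros(0)
        V = np.zeros((0, 0))
        k = 0

    nan_mask = np.isnan(Y)
    has_missing = nan_mask.any()
    if has_missing:
        patterns = {}
        for i in range(N):
            key = nan_mask[i].tobytes()
            patterns.setdefault(key, []).append(i)
        patterns = {key: np.asarray(ix) for key, ix in patterns.items()
                    if np.frombuffer(key, dtype=bool).any()}
    col_mean = np.nanmean(Y, axis=0)
    Yw = np.where(nan_mask, col_mean, Y)

    # initial state
    sums = np.zeros((J, d))
    counts = np.zeros(J)
    np.add.at(sums, acc_idx, Yw)
    np.add.at(counts, acc_idx, 1.0)
    M = sums / counts[:, None]
    mu = M.mean(axis=0)
    Gamma = np.zeros((k, d))
    resid0 = Yw - M[acc_idx]
    Sigma_e = np.cov(resid0.T).reshape(d, d) + 1e-3 * np.eye(d)
    Sigma_s = np.cov(M.T).reshape(d, d) + 1e-3 * np.eye(d)
    Sigma_a = np.eye(d)
    w = np.ones(N)
    eye = np.eye(d)

    n_keep = sampler.n_iter // sampler.thin
    draws = {
        "gebv_var": np.zeros((n_keep, d)),
        "Sigma_e_diag": np.zeros((n_keep, d)),
        "Sigma_s_diag": np.zeros((n_keep, d)),
        "marker_h2": np.zeros((n_keep, d)),
        "broad_h2": np.zeros((n_keep, d)),
    }
    M_acc = np.zeros((J, d))
    mu_acc = np.zeros(d)
    Gamma_acc = np.zeros((k, d))
    Se_acc = np.zeros((d, d))
    Ss_acc = np.zeros((d, d))
    Sa_acc = np.zeros((d, d))
    kept = 0

    total = sampler.n_burnin + sampler.n_iter
    for it in range(total):
        Se_inv = np.linalg.inv(Sigma_e)
        Ss_inv = np.linalg.inv(Sigma_s)

        # --- impute missing entries from conditional normals ---
        if has_missing:
            Mu_rows = M[acc_idx]
            for key, rows in patterns.items():
                mis = np.frombuffer(key, dtype=bool)
                obs = ~mis
                Soo = Sigma_e[np.ix_(obs, obs)]
                Smo = Sigma_e[np.ix_(mis, obs)]
                Smm = Sigma_e[np.ix_(mis, mis)]
                K = Smo @ np.linalg.inv(Soo)
                cc = Smm - K @ Smo.T
                cc = 0.5 * (cc + cc.T)
                L = np.linalg.cholesky(cc + 1e-12 * np.eye(mis.sum()))
                dev = Yw[np.ix_(rows, np.flatnonzero(obs))] \
                    - Mu_rows[np.ix_(rows, np.flatnonzero(obs))]
                cmean = Mu_rows[np.ix_(rows, np.flatnonzero(mis))] \
                    + dev @ K.T
                z = rng.standard_normal((rows.size, int(mis.sum())))
                Yw[np.ix_(rows, np.flatnonzero(mis))] = \
                    cmean + (z @ L.T) / np.sqrt(w[rows])[:, None]

        # --- latent t scales ---
        r = Yw - M[acc_idx]
        q = np.einsum("ij,jk,ik->i", r, Se_inv, r)
        w = rng.gamma((nu + d) / 2.0, 2.0 / (nu + q))

        # --- accession means ---
        wsum = np.zeros(J)
        np.add.at(wsum, acc_idx, w)
        wy = np.zeros((J, d))
        np.add.at(wy, acc_idx, w[:, None] * Yw)
        prior_mean = mu + Uo @ Gamma
        P_stack = wsum[:, None, None] * Se_inv + Ss_inv
        b = wy @ Se_inv.T + prior_mean @ Ss_inv.T
        L = np.linalg.cholesky(P_stack)
        mean = np.linalg.solve(P_stack, b[:, :, None])[:, :, 0]
        z = rng.standard_normal((J, d, 1))
        M = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[:, :, 0]

        # --- intercept ---
        T = M - Uo @ Gamma
        P_mu = J * Ss_inv + eye / priors.intercept_variance
        b_mu = Ss_inv @ T.sum(axis=0)
        L_mu = np.linalg.cholesky(P_mu)
        mean_mu = np.linalg.solve(P_mu, b_mu)
        mu = mean_mu + np.linalg.solve(L_mu.T, rng.standard_normal(d))

        # --- marker coefficients (rows independent given orthogonal U) ---
        if k:
            Sa_inv = np.linalg.inv(Sigma_a)
            Tc = M - mu
            B = (Uo.T @ Tc) @ Ss_inv.T
            P_g = s2[:, None, None] * Ss_inv + Sa_inv
            Lg = np.linalg.cholesky(P_g)
            mean_g = np.linalg.solve(P_g, B[:, :, None])[:, :, 0]
            zg = rng.standard_normal((k, d, 1))
            Gamma = mean_g + np.linalg.solve(
                np.transpose(Lg, (0, 2, 1)), zg)[:, :, 0]

        # --- covariances ---
        r = Yw - M[acc_idx]
        scat_e = (r * w[:, None]).T @ r
        Sigma_e = stats.invwishart.rvs(
            df=priors.wishart_df_error + N, scale=eye + scat_e,
            random_state=rng).reshape(d, d)

        resid_s = M - mu - Uo @ Gamma
        scat_s = resid_s.T @ resid_s
        Sigma_s = stats.invwishart.rvs(
            df=priors.wishart_df_strain + J, scale=eye + scat_s,
            random_state=rng).reshape(d, d)

        if k:
            scat_a = Gamma.T @ Gamma
            Sigma_a = stats.invwishart.rvs(
                df=priors.wishart_df_marker + k, scale=eye + scat_a,
                random_state=rng).reshape(d, d)

        if not (np.isfinite(M).all() and np.isfinite(Sigma_e).all()):
            raise FloatingPointError(
                f"sampler state went non-finite at iteration {it}")

        # --- record ---
        post = it - sampler.n_burnin
        if post >= 0 and (post + 1) % sampler.thin == 0 and kept < n_keep:
            gebv = Uo @ Gamma
            gebv_var = np.einsum("jp,jp->p", gebv, gebv) / max(J - 1, 1)
            se_d = np.diag(Sigma_e)
            ss_d = np.diag(Sigma_s)
            tot = gebv_var + ss_d + se_d
            draws["gebv_var"][kept] = gebv_var
            draws["Sigma_e_diag"][kept] = se_d
            draws["Sigma_s_diag"][kept] = ss_d
            draws["marker_h2"][kept] = gebv_var / tot
            draws["broad_h2"][kept] = (gebv_var + ss_d) / tot
            M_acc += M
            mu_acc += mu
            if k:
                Gamma_acc += Gamma
                Sa_acc += Sigma_a
            Se_acc += Sigma_e
            Ss_acc += Sigma_s
            kept += 1

    if kept == 0:
        raise ValueError("no posterior draws kept; increase n_iter")
    M_post = M_acc / kept
    diagnostics = {
        "split_rhat_Sigma_e_diag":
            [_split_rhat(draws["Sigma_e_diag"][:, p]) for p in range(d)],
        "split_rhat_Sigma_s_diag":
            [_split_rhat(draws["Sigma_s_diag"][:, p]) for p in range(d)],
        "n_draws": kept,
    }
    worst = np.nanmax(np.asarray(
        diagnostics["split_rhat_Sigma_e_diag"]
        + diagnostics["split_rhat_Sigma_s_diag"], dtype=float))
    diagnostics["max_split_rhat"] = float(worst)
    if worst > 1.1:
        warnings.warn(f"split-Rhat {worst:.3f} > 1.1 on a covariance "
                      "diagonal; consider longer chains", RuntimeWarning)

    Gamma_mean = V @ (Gamma_acc / kept) if k else np.zeros((0, d))
    return AccessionMeans(
        M=pd.DataFrame(M_post, index=acc_ids, columns=traits),
        intercept=pd.Series(mu_acc / kept, index=traits),
        marker_coefficients=Gamma_mean,
        Sigma_e=Se_acc / kept,
        Sigma_s=Ss_acc / kept,
        Sigma_a=(Sa_acc / kept) if k else None,
        draws=draws,
        diagnostics=diagnostics,
        n_accessions=J,
        traits=traits,
        accession_ids=list(acc_ids),
    )


def heritability(fit: AccessionMeans,
                 n_accessions: int | None = None) -> HeritabilityReport:
    """Per-trait marker and broad-sense heritability from posterior draws.

    For each kept draw, with GEBV variance
    ``v_p = (U Gamma)_.p' (U Gamma)_.p / (N_acc - 1)``:

        marker_h2 = v / (v + Sigma_s_pp + Sigma_e_pp)
        broad_h2  = (v + Sigma_s_pp) / (v + Sigma_s_pp + Sigma_e_pp)

    computed per draw, then summarised by posterior mean and central 95%
    interval (never a ratio of averaged numerators/denominators).
    """
    d = len(fit.traits)
    gebv = fit.draws["gebv_var"]
    ss = fit.draws["Sigma_s_diag"]
    se = fit.draws["Sigma_e_diag"]
    if n_accessions is not None and n_accessions != fit.n_accessions:
        # rescale the stored GEBV variance to the requested denominator
        gebv = gebv * (fit.n_accessions - 1) / max(n_accessions - 1, 1)
    tot = gebv + ss + se
    if np.any(tot <= 0):
        raise UndefinedHeritabilityError("zero total phenotypic variance")
    marker = gebv / tot
    broad = (gebv + ss) / tot
    table = pd.DataFrame({
        "trait": fit.traits,
        "gebv_variance": gebv.mean(axis=0),
        "marker_h2": marker.mean(axis=0),
        "marker_h2_lo": np.percentile(marker, 2.5, axis=0),
        "marker_h2_hi": np.percentile(marker, 97.5, axis=0),
        "broad_h2": broad.mean(axis=0),
        "broad_h2_lo": np.percentile(broad, 2.5, axis=0),
        "broad_h2_hi": np.percentile(broad, 97.5, axis=0),
    }).set_index("trait")
    return HeritabilityReport(table=table,
                              draws={"marker_h2": marker, "broad_h2": broad,
                                     "gebv_variance": gebv})
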