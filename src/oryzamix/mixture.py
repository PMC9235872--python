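"""Variational-Bayes Gaussian mixture with Dirichlet shrinkage.

Accession trait means are modelled as a finite mixture of multivariate
Gaussians, each group with its own mean and covariance:

    z_j  ~ Categorical(pi),   pi ~ Dirichlet(alpha)
    mu_m | Lambda_m ~ N(0, lambda0 * Lambda_m^-1)
    Lambda_m ~ Wishart(Sigma0, nu0)          (precision scale)
    x_j | z_j = m ~ N(mu_m, Lambda_m^-1)

Inference is coordinate-ascent variational Bayes on the conjugate
Dirichlet / Normal-Wishart family. A small Dirichlet concentration
(``alpha``, default 0.1) shrinks unsupported components to (near) zero
occupancy, so the number of *non-empty* groups — groups holding at least two
accessions at hard assignment — estimates the supported group count; the
deviance information criterion (DIC) over multiple random starts selects the
best fit. Responsibilities from repeated starts are aligned by Hungarian
matching and averaged, mirroring how stable group membership is reported.

Traits are standardised (zero mean, unit variance) before fitting by
default: the zero-centred prior on group means presumes centred data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "MixturePriors", "MixtureFit", "AveragedAssignment",
    "fit_vb", "dic", "plugin_loglik", "expected_loglik",
    "multi_start", "average_runs", "group_sweep",
]


@dataclass
class MixturePriors:
    """Conjugate prior hyperparameters.

    alpha : Dirichlet concentration per component (small => shrinkage).
    lambda0 : prior scale of the group-mean covariance (mean covariance is
        ``lambda0 * Sigma_m``); the Normal-Wishart beta0 is 1/lambda0.
    nu0 : Wishart degrees of freedom (default d + 2).
    Sigma0 : Wishart scale matrix on the precision scale. Default
        ``I / nu0``, so the prior expected precision is the identity —
        matching the unit variance of standardised traits. (A plain
        identity scale would put the prior expected precision at ``nu0 * I``
        and bias the model toward many small, tight components, defeating
        the Dirichlet shrinkage.)
    """

    alpha: float = 0.1
    lambda0: float = 1.0
    nu0: float | None = None
    Sigma0: np.ndarray | None = None

    def resolve(self, d: int) -> tuple[float, float, float, np.ndarray]:
        if self.alpha <= 0 or self.lambda0 <= 0:
            raise ValueError("alpha and lambda0 must be positive")
        nu0 = float(self.nu0) if self.nu0 is not None else d + 2.0
        if nu0 < d:
            raise ValueError("nu0 must be >= trait count")
        Sigma0 = (np.asarray(self.Sigma0, float) if self.Sigma0 is not None
                  else np.eye(d) / nu0)
        return self.alpha, 1.0 / self.lambda0, nu0, Sigma0


@dataclass
class MixtureFit:
    """One converged VB run."""

    n_groups_prior: int
    group_means: np.ndarray               # N_G x d (standardised scale)
    group_covariances: list               # expected covariances E[Lambda]^-1
    weights: np.ndarray                   # E[pi]
    responsibilities: np.ndarray          # n x N_G, rows sum to 1
    dic: float
    n_nonempty: int
    elbo_trace: np.ndarray
    seed: int
    converged: bool
    standardize: bool
    scale_center: np.ndarray | None = None
    scale_scale: np.ndarray | None = None
    _vb_state: dict = field(default_factory=dict, repr=False)

    @property
    def hard_labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


@dataclass
class AveragedAssignment:
    """Responsibilities averaged across label-aligned runs."""

    mean_responsibilities: np.ndarray     # n x N_G
    hard_labels: np.ndarray
    merged_labels: np.ndarray | None
    merge_map: dict | None
    run_count: int

    def merged_probabilities(self) -> np.ndarray:
        """Columns summed according to the merge map (identity if none)."""
        if not self.merge_map:
            return self.mean_responsibilities
        groups = sorted(self.merge_map)
        out = np.stack([self.mean_responsibilities[:, self.merge_map[g]]
                        .sum(axis=1) for g in groups], axis=1)
        return out


def _as_matrix(means) -> np.ndarray:
    X = means.to_numpy(float) if isinstance(means, pd.DataFrame) \
        else np.asarray(means, float)
    if X.ndim != 2:
        raise ValueError("means matrix must be 2-D")
    if np.isnan(X).any():
        raise ValueError("means matrix contains missing values; impute or "
                         "drop traits upstream")
    return X


def _log_wishart_B(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    return (-0.5 * nu * logdet - 0.5 * nu * d * np.log(2.0)
            - 0.25 * d * (d - 1) * np.log(np.pi)
            - gammaln(0.5 * (nu - np.arange(d))).sum())


def fit_vb(means, n_groups: int, priors: MixturePriors | None = None,
           seed: int = 0, max_iter: int = 2000, tol: float = 1e-8,
           standardize: bool = True, init_soften: float = 0.0,
           init_responsibilities: np.ndarray | None = None) -> MixtureFit:
    """Coordinate-ascent VB for the Dirichlet / Normal-Wishart mixture.

    Iterates until the relative ELBO change drops below ``tol`` (default
    1e-8) or ``max_iter`` sweeps. The ELBO trace is returned and is
    non-decreasing up to numerical round-off.

    Raises
    ------
    ValueError
        If ``n_groups >= n_accessions`` or the means contain NaN.
    """
    X = _as_matrix(means)
    n, d = X.shape
    if not 1 <= n_groups < n:
        raise ValueError("need 1 <= n_groups < n_accessions")
    center = scale = None
    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        X = (X - center) / scale
    priors = priors or MixturePriors()
    alpha0, beta0, nu0, W0_scale = priors.resolve(d)
    W0_inv = np.linalg.inv(W0_scale)
    K = n_groups
    rng = np.random.default_rng(seed)

    if init_responsibilities is not None:
        R = np.asarray(init_responsibilities, float)
        if R.shape != (n, K):
            raise ValueError("init_responsibilities shape mismatch")
    elif K == 1:
        R = np.ones((n, 1))
    else:
        km = KMeans(n_clusters=K, n_init=10, init="k-means++",
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(X)
        # init_soften blends the one-hot k-means assignment with a uniform
        # one; softened starts let unsupported components drain early, at
        # the cost of sometimes under-splitting — DIC arbitrates across a
        # diversified multi-start
        s = float(np.clip(init_soften, 0.0, 1.0))
        R = np.full((n, K), max(s / K, 1e-6))
        R[np.arange(n), labels] += 1.0 - s
        R /= R.sum(axis=1, keepdims=True)

    ln2pi = np.log(2.0 * np.pi)
    elbo_trace = []
    converged = False
    prev = -np.inf
    still = 0
    patience = 10
    ridge_warned = False

    for _ in range(max_iter):
        # ----- M step: update variational parameters from R -----
        Nk = R.sum(axis=0) + 1e-300
        xbar = (R.T @ X) / Nk[:, None]
        alpha_k = alpha0 + R.sum(axis=0)
        beta_k = beta0 + Nk
        nu_k = nu0 + Nk
        m_k = (Nk[:, None] * xbar) / beta_k[:, None]   # m0 = 0
        W_k = np.empty((K, d, d))
        for k in range(K):
            diff = X - xbar[k]
            Sk = (R[:, k][:, None] * diff).T @ diff
            dev = xbar[k]                               # xbar - m0
            Winv = W0_inv + Sk + (beta0 * Nk[k] / beta_k[k]) * np.outer(dev, dev)
            try:
                W_k[k] = np.linalg.inv(Winv)
            except np.linalg.LinAlgError:
                if not ridge_warned:
                    warnings.warn("singular covariance update; applying "
                                  "ridge", RuntimeWarning)
                    ridge_warned = True
                W_k[k] = np.linalg.inv(Winv + 1e-8 * np.trace(Winv) / d
                                       * np.eye(d))

        # ----- E step -----
        ln_pi = digamma(alpha_k) - digamma(alpha_k.sum())
        ln_lam = np.empty(K)
        quad = np.empty((n, K))
        for k in range(K):
            _, logdet = np.linalg.slogdet(W_k[k])
            ln_lam[k] = (digamma(0.5 * (nu_k[k] - np.arange(d))).sum()
                         + d * np.log(2.0) + logdet)
            diff = X - m_k[k]
            quad[:, k] = (d / beta_k[k]
                          + nu_k[k] * np.einsum("ij,jk,ik->i", diff,
                                                W_k[k], diff))
        ln_rho = ln_pi + 0.5 * ln_lam - 0.5 * d * ln2pi - 0.5 * quad
        ln_norm = logsumexp(ln_rho, axis=1)
        R = np.exp(ln_rho - ln_norm[:, None])

        # ----- ELBO -----
        Nk = R.sum(axis=0) + 1e-300
        xbar = (R.T @ X) / Nk[:, None]
        e_lik = 0.0
        for k in range(K):
            diff = X - xbar[k]
            Sk = (R[:, k][:, None] * diff).T @ diff / Nk[k]
            dbar = xbar[k] - m_k[k]
            e_lik += 0.5 * Nk[k] * (
                ln_lam[k] - d / beta_k[k]
                - nu_k[k] * np.trace(Sk @ W_k[k])
                - nu_k[k] * dbar @ W_k[k] @ dbar - d * ln2pi)
        e_z = float(np.sum(R * ln_pi))
        lnC0 = gammaln(K * alpha0) - K * gammaln(alpha0)
        e_pi = lnC0 + (alpha0 - 1.0) * ln_pi.sum()
        e_mu_lam = 0.0
        for k in range(K):
            e_mu_lam += 0.5 * (d * np.log(beta0 / (2 * np.pi)) + ln_lam[k]
                               - d * beta0 / beta_k[k]
                               - beta0 * nu_k[k] * m_k[k] @ W_k[k] @ m_k[k])
            e_mu_lam += (_log_wishart_B(W0_scale, nu0)
                         + 0.5 * (nu0 - d - 1) * ln_lam[k]
                         - 0.5 * nu_k[k] * np.trace(W0_inv @ W_k[k]))
        with np.errstate(divide="ignore", invalid="ignore"):
            q_z = float(np.sum(np.where(R > 0, R * np.log(R), 0.0)))
        q_pi = (gammaln(alpha_k.sum()) - gammaln(alpha_k).sum()
                + float(((alpha_k - 1.0) * ln_pi).sum()))
        q_mu_lam = 0.0
        for k in range(K):
            H_w = (-_log_wishart_B(W_k[k], nu_k[k])
                   - 0.5 * (nu_k[k] - d - 1) * ln_lam[k]
                   + 0.5 * nu_k[k] * d)
            q_mu_lam += (0.5 * ln_lam[k]
                         + 0.5 * d * np.log(beta_k[k] / (2 * np.pi))
                         - 0.5 * d - H_w)
        elbo = e_lik + e_z + e_pi + e_mu_lam - q_z - q_pi - q_mu_lam
        elbo_trace.append(elbo)
        # a single sub-tolerance step can be a lull while an unsupported
        # component drains slowly, so demand several in a row
        if np.isfinite(prev) and abs(elbo - prev) <= tol * abs(prev):
            still += 1
            if still >= patience:
                converged = True
                break
        else:
            still = 0
        prev = elbo

    state = {"alpha": alpha_k, "beta": beta_k, "nu": nu_k, "m": m_k,
             "W": W_k, "ln_pi": ln_pi, "ln_lam": ln_lam}
    covs = [np.linalg.inv(nu_k[k] * W_k[k]) for k in range(K)]
    hard = R.argmax(axis=1)
    n_nonempty = int(np.sum(np.bincount(hard, minlength=K) >= 2))
    fit = MixtureFit(
        n_groups_prior=K, group_means=m_k, group_covariances=covs,
        weights=alpha_k / alpha_k.sum(), responsibilities=R,
        dic=np.nan, n_nonempty=n_nonempty,
        elbo_trace=np.asarray(elbo_trace), seed=seed, converged=converged,
        standardize=standardize, scale_center=center, scale_scale=scale,
        _vb_state=state)
    fit.dic = dic(fit, means)
    return fit


def _standardised(fit: MixtureFit, means) -> np.ndarray:
    X = _as_matrix(means)
    if fit.standardize:
        X = (X - fit.scale_center) / fit.scale_scale
    return X


def plugin_loglik(fit: MixtureFit, means) -> float:
    """Mixture log-likelihood at the variational posterior means."""
    X = _standardised(fit, means)
    n, d = X.shape
    st = fit._vb_state
    K = fit.n_groups_prior
    ln2pi = np.log(2.0 * np.pi)
    log_pdf = np.empty((n, K))
    pi_hat = st["alpha"] / st["alpha"].sum()
    for k in range(K):
        prec = st["nu"][k] * st["W"][k]
        _, logdet = np.linalg.slogdet(prec)
        diff = X - st["m"][k]
        qf = np.einsum("ij,jk,ik->i", diff, prec, diff)
        log_pdf[:, k] = (np.log(pi_hat[k]) + 0.5 * logdet
                         - 0.5 * d * ln2pi - 0.5 * qf)
    return float(logsumexp(log_pdf, axis=1).sum())


def expected_loglik(fit: MixtureFit, means) -> float:
    """Expected mixture log-likelihood under the variational posterior.

    Uses the variational expectations of ``log pi`` and of the Gaussian
    quadratic form (including the ``d/beta`` mean-uncertainty term).
    """
    X = _standardised(fit, means)
    n, d = X.shape
    st = fit._vb_state
    K = fit.n_groups_prior
    ln2pi = np.log(2.0 * np.pi)
    log_f = np.empty((n, K))
    for k in range(K):
        diff = X - st["m"][k]
        qf = (d / st["beta"][k]
              + st["nu"][k] * np.einsum("ij,jk,ik->i", diff, st["W"][k], diff))
        log_f[:, k] = (st["ln_pi"][k] + 0.5 * st["ln_lam"][k]
                       - 0.5 * d * ln2pi - 0.5 * qf)
    return float(logsumexp(log_f, axis=1).sum())


def dic(fit: MixtureFit, means) -> float:
    """Deviance information criterion of a converged VB fit.

    ``DIC = -2 * loglik(posterior means) + 2 * p_D`` with
    ``p_D = 2 * (loglik(posterior means) - E_q[loglik])``, i.e. the
    classic ``Dbar + p_D`` with a variational expected deviance; ``p_D >= 0``
    at the optimum up to round-off. Lower DIC = better fit.
    """
    ll_hat = plugin_loglik(fit, means)
    ll_bar = expected_loglik(fit, means)
    if not np.isfinite(ll_hat) or not np.isfinite(ll_bar):
        raise FloatingPointError("non-finite mixture likelihood")
    p_d = 2.0 * (ll_hat - ll_bar)
    return -2.0 * ll_hat + 2.0 * p_d


def multi_start(means, n_groups: int, priors: MixturePriors | None = None,
                n_starts: int = 20, seed: int = 0, seeds=None,
                diversify: bool = False,
                **fit_kwargs) -> tuple[list, MixtureFit]:
    """Independent VB runs from distinct initialisations; best = lowest DIC.

    With ``diversify=True`` every other start softens its initial
    responsibilities toward uniform, adding shrinkage-friendly basins in
    which unsupported components can drain; useful when the point of the
    fit is counting supported groups (see :func:`group_sweep`) rather than
    refining a known partition.

    Returns ``(fits, best)``; per-start DIC values are available as
    ``[f.dic for f in fits]``.
    """
    if seeds is None:
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        seeds = [seed + 1000 * s for s in range(n_starts)]
    fits, failures = [], []
    n_acc = _as_matrix(means).shape[0]
    for i, s in enumerate(seeds):
        kw = dict(fit_kwargs)
        if diversify:
            if i == len(seeds) - 1 and n_groups > 1:
                # explicitly collapsed start: the "no structure" candidate
                R0 = np.full((n_acc, n_groups), 1e-9)
                R0[:, 0] = 1.0
                kw.setdefault("init_responsibilities",
                              R0 / R0.sum(axis=1, keepdims=True))
            else:
                kw.setdefault("init_soften", 0.75 if i % 2 else 0.0)
        try:
            fits.append(fit_vb(means, n_groups, priors, seed=int(s), **kw))
        except (np.linalg.LinAlgError, FloatingPointError) as exc:
            failures.append((s, exc))
    if not fits:
        raise RuntimeError(f"all {len(failures)} starts failed; first: "
                           f"{failures[0][1]!r}")
    best = min(fits, key=lambda f: f.dic)
    return fits, best


def _align(R_run: np.ndarray, R_ref: np.ndarray) -> np.ndarray:
    """Column permutation of R_run maximising correlation with R_ref."""
    K = R_ref.shape[1]
    C = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            ra, rb = R_ref[:, a], R_run[:, b]
            if ra.std() == 0 or rb.std() == 0:
                C[a, b] = 0.0
            else:
                C[a, b] = np.corrcoef(ra, rb)[0, 1]
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return R_run[:, perm]


def average_runs(fits: list, reference: MixtureFit | None = None,
                 merge_map: dict | None = None) -> AveragedAssignment:
    """Align runs to a reference by Hungarian matching and average.

    ``merge_map`` maps merged-label -> list of original group indices (e.g.
    ``{0: [0], 1: [1, 2], 2: [3]}`` to pool the two intermediate groups);
    it must partition ``range(N_G)``.
    """
    if not fits:
        raise ValueError("no fits to average")
    K = fits[0].n_groups_prior
    n = fits[0].responsibilities.shape[0]
    for f in fits:
        if f.n_groups_prior != K or f.responsibilities.shape[0] != n:
            raise ValueError("fits disagree on N_G or accession count")
    reference = reference or min(fits, key=lambda f: f.dic)
    acc = np.zeros((n, K))
    for f in fits:
        acc += _align(f.responsibilities, reference.responsibilities)
    mean_R = acc / len(fits)
    # ties broken toward the lowest group index (argmax default)
    hard = mean_R.argmax(axis=1)
    merged = None
    if merge_map is not None:
        members = sorted(g for gs in merge_map.values() for g in gs)
        if members != list(range(K)):
            raise ValueError("merge_map must partition group labels")
        lookup = {g: lab for lab, gs in merge_map.items() for g in gs}
        merged_R = AveragedAssignment(mean_R, hard, None, merge_map,
                                      len(fits)).merged_probabilities()
        merged = merged_R.argmax(axis=1)
        merged = np.asarray(sorted(merge_map))[merged]
        _ = lookup
    return AveragedAssignment(mean_responsibilities=mean_R, hard_labels=hard,
                              merged_labels=merged, merge_map=merge_map,
                              run_count=len(fits))


def group_sweep(means, n_groups_range, priors: MixturePriors | None = None,
                n_starts: int = 5, seed: int = 0, dic_tie_tol: float = 1e-2,
                **fit_kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit across a range of a-priori group numbers.

    Starts are diversified (half hard k-means, half softened) so that both
    finely-split and collapsed candidate solutions compete on DIC at every
    N_G. Fits whose DIC lies within ``dic_tie_tol`` (relative, default
    1% — the conventional scale below which fits from different starts are
    called consistent) of the minimum are treated as statistically
    equivalent, and the most parsimonious of them — fewest non-empty
    groups — is reported, since the sweep's purpose is counting supported
    groups. Returns
    ``(table, trajectories)``: one row per N_G with the best DIC and the
    chosen fit's non-empty group count, plus per-accession hard labels
    across N_G in long form (accession, n_groups, label) for Sankey-style
    tracking.
    """
    rows, traj = [], []
    for i, K in enumerate(n_groups_range):
        fits, best = multi_start(means, int(K), priors, n_starts=n_starts,
                                 seed=seed + 17 * i, diversify=True,
                                 **fit_kwargs)
        ties = [f for f in fits
                if f.dic - best.dic <= dic_tie_tol * abs(best.dic)]
        chosen = min(ties, key=lambda f: (f.n_nonempty, f.dic))
        avg = average_runs(fits, reference=chosen)
        rows.append({"n_groups": int(K), "best_dic": best.dic,
                     "n_nonempty": chosen.n_nonempty,
                     "dic_spread": float(np.ptp([f.dic for f in fits]))})
        for j, lab in enumerate(avg.hard_labels):
            traj.append({"accession_index": j, "n_groups": int(K),
                         "label": int(lab)})
    return pd.DataFrame(rows), pd.DataFrame(traj)
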