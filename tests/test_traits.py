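"""Trait diagnostics: Hotelling ranking oracle, correlation tests,
subset selection and refits."""

import numpy as np
import pandas as pd
import pytest

from oryzamix.traits import (correlation_switch_test, group_correlations,
                             hotelling_rank, refit_with_subset,
                             select_subsets)


def _responsibilities(labels, K):
    R = np.zeros((len(labels), K))
    R[np.arange(len(labels)), labels] = 1.0
    return R


def _oracle_t2(X, Y):
    """Brute-force normal-equations Hotelling T² (independent of the
    implementation's code path)."""
    n, d = X.shape
    Xs = (X - X.mean(0)) / X.std(0)
    D = np.hstack([np.ones((n, 1)), Xs])
    q = d + 1
    C = np.linalg.inv(D.T @ D)
    B = C @ D.T @ Y
    E = Y - D @ B
    S = E.T @ E / (n - q)
    out = np.empty(d)
    for t in range(d):
        b = B[t + 1]
        V = C[t + 1, t + 1] * S
        out[t] = b @ np.linalg.inv(V) @ b / (n - q)
    return out


class TestHotelling:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        n, d = 20, 4
        X = pd.DataFrame(rng.standard_normal((n, d)),
                         columns=list("wxyz"))
        labels = rng.integers(0, 3, n)
        R = _responsibilities(labels, 3)
        Y = np.stack([R[:, 0], R[:, 1]], axis=1)
        got = hotelling_rank(X, R).reindex(list("wxyz")).to_numpy()
        want = _oracle_t2(X.to_numpy(), Y)
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_ranking_invariant_to_trait_rescaling(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((30, 4)),
                         columns=list("abcd"))
        R = _responsibilities(rng.integers(0, 3, 30), 3)
        base = hotelling_rank(X, R)
        X2 = X.copy()
        X2["b"] = X2["b"] * 1000 + 5
        scaled = hotelling_rank(X2, R)
        assert list(base.index) == list(scaled.index)
        np.testing.assert_allclose(base.to_numpy(), scaled.to_numpy(),
                                   rtol=1e-8)

    def test_perfect_predictor_ranks_first(self):
        rng = np.random.default_rng(2)
        n = 24
        labels = np.repeat([0, 1, 2], 8)
        R = _responsibilities(labels, 3)
        X = pd.DataFrame({
            "signal": labels * 2.0 + rng.normal(0, 0.01, n),
            "n1": rng.standard_normal(n),
            "n2": rng.standard_normal(n),
        })
        assert hotelling_rank(X, R).index[0] == "signal"

    def test_null_trait_below_permutation_tail(self):
        rng = np.random.default_rng(3)
        n = 60
        labels = np.repeat([0, 1, 2], 20)
        R = _responsibilities(labels, 3)
        X = pd.DataFrame({
            "signal": labels + rng.normal(0, 0.3, n),
            "null": rng.standard_normal(n),
        })
        obs = hotelling_rank(X, R)["null"]
        null_stats = []
        for _ in range(200):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp["null"] = X["null"].to_numpy()[perm]
            null_stats.append(hotelling_rank(Xp, R)["null"])
        assert obs < np.percentile(null_stats, 95)

    def test_requires_three_groups(self):
        X = pd.DataFrame(np.random.default_rng(4).standard_normal((10, 2)))
        with pytest.raises(ValueError):
            hotelling_rank(X, _responsibilities(np.zeros(10, int), 2))


class TestGroupCorrelations:
    def test_duplicated_trait_correlates_perfectly_everywhere(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.standard_normal(30)})
        X["b"] = X["a"]
        labels = np.repeat([0, 1], 15)
        out = group_correlations(X, labels)
        for g in (0, 1):
            assert out[g].loc["a", "b"] == pytest.approx(1.0)

    def test_random_split_gives_similar_correlations(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((600, 2))
        X = pd.DataFrame({"a": Z[:, 0], "b": 0.7 * Z[:, 0] + 0.3 * Z[:, 1]})
        labels = rng.integers(0, 3, 600)
        out = group_correlations(X, labels)
        vals = [out[g].loc["a", "b"] for g in out]
        assert np.ptp(vals) < 0.15

    def test_small_group_excluded_with_warning(self):
        X = pd.DataFrame(np.random.default_rng(7).standard_normal((10, 2)))
        labels = np.array([0] * 8 + [1] * 2)
        with pytest.warns(RuntimeWarning):
            out = group_correlations(X, labels)
        assert 1 not in out


class TestSwitchTest:
    def test_seeded_permutations_bit_reproducible(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((40, 3)))
        labels = np.repeat([0, 1], 20)
        a = correlation_switch_test(X, labels, n_permutations=99, seed=1)
        b = correlation_switch_test(X, labels, n_permutations=99, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_pvalues_respect_lower_bound(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((40, 4)))
        labels = np.repeat([0, 1], 20)
        pv = correlation_switch_test(X, labels, n_permutations=49, seed=2)
        assert (pv["p_value"] >= 1 / 50).all()
        assert (pv["p_value"] <= 1.0).all()

    def test_opposite_correlations_detected(self):
        rng = np.random.default_rng(10)
        n = 60
        rho = 0.8
        L_pos = np.linalg.cholesky([[1, rho], [rho, 1]])
        L_neg = np.linalg.cholesky([[1, -rho], [-rho, 1]])
        X = np.vstack([rng.standard_normal((n, 2)) @ L_pos.T,
                       rng.standard_normal((n, 2)) @ L_neg.T])
        labels = np.repeat([0, 1], n)
        pv = correlation_switch_test(pd.DataFrame(X, columns=["a", "b"]),
                                     labels, n_permutations=999, seed=3)
        assert pv["p_value"].iloc[0] == 1 / 1000


class TestSubsets:
    def _diag(self):
        t2 = pd.Series({"a": 0.7, "b": 0.3, "c": 0.1, "d": 0.05})
        pv = pd.DataFrame({"trait_a": ["a", "c"], "trait_b": ["b", "d"],
                           "observed_range": [1.0, 0.9],
                           "p_value": [0.0005, 0.01]})
        return t2, pv

    def test_threshold_selection(self):
        t2, pv = self._diag()
        out = select_subsets(t2, pv, t2_threshold=0.17, p_threshold=0.001)
        assert out["by_value"] == ["a", "b"]
        assert out["by_correlation"] == ["a", "b"]
        assert out["union"] == ["a", "b"]

    def test_extreme_thresholds(self):
        t2, pv = self._diag()
        with pytest.warns(RuntimeWarning):
            out = select_subsets(t2, pv, t2_threshold=np.inf,
                                 p_threshold=0.0)
        assert out["by_value"] == []
        out2 = select_subsets(t2, pv, t2_threshold=-1, p_threshold=1.0)
        assert set(out2["by_correlation"]) == {"a", "b", "c", "d"}
        assert len(out2["by_value"]) == 4

    def test_refit_with_all_traits_reproduces_partition(self,
                                                        three_group_dataset):
        means = three_group_dataset.true_accession_means
        truth = three_group_dataset.true_groups.to_numpy()
        avg, ari = refit_with_subset(means, list(means.columns), truth,
                                     n_groups=3, n_starts=5, seed=4)
        assert ari >= 0.99

    def test_uninformative_subset_degrades_agreement(self,
                                                     three_group_dataset):
        rng = np.random.default_rng(11)
        means = three_group_dataset.true_accession_means.copy()
        truth = three_group_dataset.true_groups.to_numpy()
        means["junk1"] = rng.standard_normal(len(means))
        means["junk2"] = rng.standard_normal(len(means))
        means["junk3"] = rng.standard_normal(len(means))
        _, ari_good = refit_with_subset(means, list(means.columns[:5]),
                                        truth, n_groups=3, n_starts=5,
                                        seed=5)
        _, ari_junk = refit_with_subset(means, ["junk1", "junk2", "junk3"],
                                        truth, n_groups=3, n_starts=5,
                                        seed=5)
        assert ari_good > ari_junk + 0.5
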