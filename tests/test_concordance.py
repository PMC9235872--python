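"""Concordance tables, admixture partitioning, core selection, Sankey links."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oryzamix.concordance import (admixture_partition, crosstab,
                                  normalize_species, sankey_links,
                                  select_core)


@pytest.fixture
def toy_metadata():
    return pd.DataFrame({
        "accession_id": ["a1", "a2", "a3", "a4", "a5"],
        "species": ["O. rufipogon", "O. nivara", "Oryza spp.",
                    "Oryza hybr.", "O. rufipogon"],
        "subpopulation": ["W1", "W2", "ADM/OSAT", "W4", "W3"],
        "osat_admixture_fraction": [0.05, 0.1, 0.6, 0.85, np.nan],
    })


class TestCrosstab:
    def test_counts_match_hand_enumeration(self, toy_metadata):
        labels = pd.Series(["P1", "P4", "P2", "P2", "P1"],
                           index=["a1", "a2", "a3", "a4", "a5"])
        res = crosstab(toy_metadata, labels, by="species")
        assert res.counts.loc["P1", "O. rufipogon"] == 2
        assert res.counts.loc["P4", "O. nivara"] == 1
        # Oryza hybr. pooled into Oryza spp.
        assert res.counts.loc["P2", "Oryza spp."] == 2
        assert res.counts.to_numpy().sum() == 5
        np.testing.assert_allclose(res.row_percent.sum(axis=1), 100.0)

    def test_unmatched_accessions_reported(self, toy_metadata):
        labels = pd.Series(["P1", "P1"], index=["a1", "zz"])
        res = crosstab(toy_metadata, labels)
        assert res.unmatched == ["zz"]
        assert res.counts.to_numpy().sum() == 1

    def test_diagonal_under_perfect_concordance(self):
        from oryzamix.simulate import SimulationConfig, simulate_dataset
        sim = simulate_dataset(SimulationConfig(
            n_accessions=60, n_snps=100, n_traits=3,
            species_concordance=1.0, seed=2))
        labels = pd.Series(sim.true_groups.to_numpy(),
                           index=sim.accession_ids)
        res = crosstab(sim.metadata, labels)
        # each phenotypic group maps to exactly one species
        assert ((res.counts > 0).sum(axis=1) == 1).all()


class TestAdmixture:
    def test_boundary_is_strict(self):
        meta = pd.DataFrame({"accession_id": ["x"], "species": ["O. nivara"],
                             "subpopulation": ["W2"],
                             "osat_admixture_fraction": [0.5]})
        labels, _ = admixture_partition(meta, threshold=0.5)
        assert labels.loc["x"] == "W2"

    def test_toy_fractions(self):
        meta = pd.DataFrame({
            "accession_id": ["a", "b", "c"],
            "subpopulation": ["W1", "W2", "W5"],
            "osat_admixture_fraction": [0.1, 0.6, 0.85]})
        labels, _ = admixture_partition(meta, threshold=0.5)
        flagged = labels[labels == "ADM/OSAT"].index
        assert set(flagged) == {"b", "c"}
        assert meta.set_index("accession_id").loc[
            flagged, "osat_admixture_fraction"].mean() == pytest.approx(0.725)

    def test_alternative_thresholds(self):
        meta = pd.DataFrame({
            "accession_id": list("abcd"),
            "subpopulation": ["W1"] * 4,
            "osat_admixture_fraction": [0.15, 0.3, 0.45, 0.7]})
        for thr, expect in [(0.4, {"c", "d"}), (0.2, {"b", "c", "d"})]:
            labels, _ = admixture_partition(meta, threshold=thr)
            assert set(labels[labels == "ADM/OSAT"].index) == expect

    def test_missing_fraction_flagged_unknown(self, toy_metadata):
        labels, _ = admixture_partition(toy_metadata)
        assert labels.loc["a5"] == "unknown"


class TestSelectCore:
    def _meta(self):
        return pd.DataFrame({
            "accession_id": [f"c{i}" for i in range(6)],
            "species": ["O. rufipogon"] * 3 + ["O. nivara"] * 3,
            "subpopulation": ["W1", "W3", "W6", "W2", "W5", "W2"],
            "osat_admixture_fraction": [0.01] * 6,
        })

    def test_fully_concordant_table_selected_entirely(self):
        meta = self._meta()
        groups = pd.Series(["P1"] * 3 + ["P4"] * 3,
                           index=meta["accession_id"])
        core = select_core(meta, groups)
        assert core["O. rufipogon"] == ["c0", "c1", "c2"]
        assert core["O. nivara"] == ["c3", "c4", "c5"]

    def test_admixture_threshold_excludes(self):
        meta = self._meta()
        meta.loc[0, "osat_admixture_fraction"] = 0.25
        groups = pd.Series(["P1"] * 3 + ["P4"] * 3,
                           index=meta["accession_id"])
        core = select_core(meta, groups)
        assert "c0" not in core["O. rufipogon"]

    def test_species_override_column_respected(self):
        meta = self._meta()
        meta["species_override"] = [None] * 6
        meta.loc[5, "species"] = "O. rufipogon"      # recorded species wrong
        meta.loc[5, "species_override"] = "O. nivara"
        groups = pd.Series(["P1"] * 3 + ["P4"] * 3,
                           index=meta["accession_id"])
        core = select_core(meta, groups)
        assert "c5" in core["O. nivara"]

    def test_matches_brute_force_set_intersection(self):
        rng = np.random.default_rng(3)
        n = 80
        species = rng.choice(["O. rufipogon", "O. nivara", "Oryza spp."], n)
        subpop = rng.choice(["W1", "W2", "W3", "W5", "W6", "ADM/OSAT"], n)
        frac = rng.uniform(0, 0.5, n)
        ids = [f"r{i}" for i in range(n)]
        meta = pd.DataFrame({"accession_id": ids, "species": species,
                             "subpopulation": subpop,
                             "osat_admixture_fraction": frac})
        groups = pd.Series(rng.choice(["P1", "P2", "P4"], n), index=ids)
        core = select_core(meta, groups)
        # independent enumeration
        want_ruf = sorted(
            ids[i] for i in range(n)
            if groups.iloc[i] == "P1" and species[i] == "O. rufipogon"
            and subpop[i] in {"W1", "W3", "W6"} and frac[i] < 0.2)
        want_niv = sorted(
            ids[i] for i in range(n)
            if groups.iloc[i] == "P4" and species[i] == "O. nivara"
            and subpop[i] in {"W2", "W5"} and frac[i] < 0.2)
        assert core["O. rufipogon"] == want_ruf
        assert core["O. nivara"] == want_niv


class TestSankey:
    def test_identical_labelings_only_self_links(self):
        s = pd.Series(["x", "y", "x"], index=["a", "b", "c"])
        links = sankey_links([("s1", s), ("s2", s)])
        assert (links["source_label"] == links["target_label"]).all()

    def test_single_change_yields_one_off_diagonal_link(self):
        a = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        b = a.copy()
        b.loc["a"] = "y"
        links = sankey_links([("s1", a), ("s2", b)])
        off = links[links.source_label != links.target_label]
        assert len(off) == 1 and off["count"].iloc[0] == 1
        assert off["accessions"].iloc[0] == "a"

    def test_mismatched_universe_rejected(self):
        a = pd.Series(["x"], index=["a"])
        b = pd.Series(["x"], index=["b"])
        with pytest.raises(ValueError):
            sankey_links([("s1", a), ("s2", b)])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_counts_conserved_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        ids = [f"a{i}" for i in range(n)]
        stages = [pd.Series(rng.choice(list("pqr"), n), index=ids)
                  for _ in range(3)]
        links = sankey_links([("s0", stages[0]), ("s1", stages[1]),
                              ("s2", stages[2])])
        for src in ("s0", "s1"):
            assert links.loc[links.source_stage == src, "count"].sum() == n
        perm = rng.permutation(n)
        shuffled = [s.iloc[perm] for s in stages]
        links2 = sankey_links([("s0", shuffled[0]), ("s1", shuffled[1]),
                               ("s2", shuffled[2])])
        pd.testing.assert_frame_equal(
            links.reset_index(drop=True), links2.reset_index(drop=True))


def test_species_normalisation():
    s = pd.Series(["Oryza hybr.", "O. nivara"])
    assert list(normalize_species(s)) == ["Oryza spp.", "O. nivara"]
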