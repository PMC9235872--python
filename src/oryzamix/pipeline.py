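"""End-to-end pipeline: simulate/load -> relationship -> accession means ->
mixture -> trait diagnostics -> concordance, with per-stage provenance.

Each stage writes its outputs plus a JSON provenance record (input
checksums, seeds, package version, config hash); deterministic stages
reproduce identical outputs on re-run with the same configuration. A stage
failure halts the run with a stage-tagged error and leaves a FAILED marker
next to any partial outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .concordance import admixture_partition, crosstab, sankey_links
from .hierarchical import (HierarchicalPriors, SamplerSettings,
                           fit_hierarchical, heritability)
from .mixture import MixturePriors, average_runs, group_sweep, multi_start
from .relationship import filter_non_singleton, van_raden
from .simulate import SimulationConfig, simulate_dataset
from .traits import full_diagnostics, refit_with_subset

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause!r}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, priors and run settings for one pipeline execution."""

    output_dir: str = "pipeline_out"
    observations: str | None = None       # CSV; None => simulate
    genotypes: str | None = None          # TSV or VCF; None with
                                          # observations => no-marker mode
    metadata: str | None = None
    simulation: dict = field(default_factory=dict)  # SimulationConfig kwargs
    hierarchical_priors: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)
    mixture_priors: dict = field(default_factory=dict)
    n_groups: int = 4
    n_groups_range: list = field(default_factory=lambda: [2, 3, 4, 5, 6])
    run_sweep: bool = False
    n_starts: int = 20
    n_permutations: int = 9999
    t2_threshold: float = 0.17
    p_threshold: float = 0.001
    admixture_threshold: float = 0.5
    standardize: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; return an output bundle.

    The bundle maps stage names to their in-memory results; files are
    written under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta_hdr = {"config_hash": chash, "seed": config.seed,
                "version": __version__}
    provenance = {"config_hash": chash, "version": __version__,
                  "seed": config.seed, "stages": {}}
    bundle = {}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:
                (out / "FAILED").write_text(f"{name}: {exc!r}\n")
                raise StageError(name, exc) from exc
            bundle[name] = result
            provenance["stages"][name] = {"ok": True}
            return result
        return deco

    # ---- stage: inputs (load or simulate) ----
    @stage("inputs")
    def _inputs():
        if config.observations is None:
            sim = simulate_dataset(SimulationConfig(
                seed=config.seed, **config.simulation))
            obs, meta = sim.observations, sim.metadata
            geno, acc_ids = sim.genotypes, sim.accession_ids
            io.write_observations(obs, out / "observations.csv", meta_hdr)
            io.write_table(meta, out / "metadata.csv", meta_hdr)
            io.write_genotypes_tsv(geno, acc_ids, out / "genotypes.tsv",
                                   meta_hdr)
            io.write_json({"true_groups":
                           sim.true_groups.to_dict()}, out / "truth.json")
            return {"observations": obs, "metadata": meta,
                    "genotypes": geno, "accession_ids": acc_ids,
                    "simulated": sim}
        obs = io.read_observations(config.observations)
        meta = (io.read_metadata(config.metadata)
                if config.metadata else None)
        geno = acc_ids = None
        if config.genotypes:
            p = str(config.genotypes)
            if p.endswith(".vcf") or p.endswith(".vcf.gz"):
                geno, acc_ids = io.read_genotypes_vcf(p)
            else:
                geno, acc_ids = io.read_genotypes_tsv(p)
            provenance["stages"].setdefault("inputs", {})
        for key in ("observations", "genotypes", "metadata"):
            path = getattr(config, key)
            if path:
                provenance.setdefault("inputs", {})[key] = \
                    _checksum(Path(path))
        return {"observations": obs, "metadata": meta, "genotypes": geno,
                "accession_ids": acc_ids, "simulated": None}

    inputs = bundle["inputs"]

    # ---- stage: relationship ----
    @stage("relationship")
    def _relationship():
        if inputs["genotypes"] is None:
            return None
        filtered, kept = filter_non_singleton(inputs["genotypes"])
        emb = van_raden(filtered, accession_ids=inputs["accession_ids"])
        io.write_embedding(emb, out / "relationship_G.tsv",
                           out / "relationship_U.tsv", meta_hdr)
        return emb

    # ---- stage: accession means ----
    @stage("accession_means")
    def _means():
        fit = fit_hierarchical(
            inputs["observations"],
            embedding=bundle["relationship"],
            priors=HierarchicalPriors(**config.hierarchical_priors),
            sampler=SamplerSettings(seed=config.seed + 1, **config.sampler))
        io.write_table(fit.M.reset_index(names="accession_id"),
                       out / "accession_means.csv", meta_hdr)
        her = heritability(fit)
        io.write_table(her.table.reset_index(), out / "heritability.csv",
                       meta_hdr)
        io.write_json(fit.diagnostics, out / "sampler_diagnostics.json")
        return {"fit": fit, "heritability": her}

    means_df = bundle["accession_means"]["fit"].M

    # ---- stage: mixture ----
    @stage("mixture")
    def _mixture():
        priors = MixturePriors(**config.mixture_priors)
        sweep = None
        if config.run_sweep:
            table, traj = group_sweep(means_df, config.n_groups_range,
                                      priors, n_starts=max(
                                          5, config.n_starts // 4),
                                      seed=config.seed + 2,
                                      standardize=config.standardize)
            io.write_table(table, out / "sweep.csv", meta_hdr)
            io.write_table(traj, out / "sweep_trajectories.csv", meta_hdr)
            sweep = table
        fits, best = multi_start(means_df, config.n_groups, priors,
                                 n_starts=config.n_starts,
                                 seed=config.seed + 3,
                                 standardize=config.standardize)
        avg = average_runs(fits, reference=best)
        resp = pd.DataFrame(avg.mean_responsibilities,
                            index=means_df.index,
                            columns=[f"P{m + 1}" for m in
                                     range(config.n_groups)])
        io.write_table(resp.reset_index(names="accession_id"),
                       out / "responsibilities.csv", meta_hdr)
        io.write_table(pd.DataFrame({"start_seed": [f.seed for f in fits],
                                     "dic": [f.dic for f in fits],
                                     "n_nonempty": [f.n_nonempty
                                                    for f in fits]}),
                       out / "per_start_dic.csv", meta_hdr)
        return {"fits": fits, "best": best, "averaged": avg, "sweep": sweep}

    avg = bundle["mixture"]["averaged"]

    # ---- stage: trait diagnostics ----
    @stage("traits")
    def _traits():
        diag = full_diagnostics(means_df, avg,
                                n_permutations=config.n_permutations,
                                seed=config.seed + 4,
                                t2_threshold=config.t2_threshold,
                                p_threshold=config.p_threshold)
        io.write_table(diag.t2.reset_index().rename(
            columns={"index": "trait"}), out / "hotelling_t2.csv", meta_hdr)
        io.write_table(diag.switch_pvalues, out / "switch_pvalues.csv",
                       meta_hdr)
        io.write_json(diag.subsets, out / "trait_subsets.json")
        long = []
        for g, corr in diag.group_correlations.items():
            c = corr.stack().reset_index()
            c.columns = ["trait_a", "trait_b", "correlation"]
            c.insert(0, "group", g)
            long.append(c)
        if long:
            io.write_table(pd.concat(long), out / "group_correlations.csv",
                           meta_hdr)
        return diag

    # ---- stage: subset refits ----
    @stage("subset_refits")
    def _refits():
        diag = bundle["traits"]
        results = {}
        for name, subset in diag.subsets.items():
            if not subset:
                continue
            _, ari = refit_with_subset(
                means_df, subset, avg.hard_labels,
                n_groups=max(3, config.n_groups - 1),
                n_starts=min(config.n_starts, 10),
                priors=MixturePriors(**config.mixture_priors),
                seed=config.seed + 5)
            results[name] = {"n_traits": len(subset), "ari": ari}
        io.write_json(results, out / "subset_refits.json")
        return results

    # ---- stage: concordance ----
    @stage("concordance")
    def _concordance():
        meta = inputs["metadata"]
        if meta is None:
            return None
        labels = pd.Series([f"P{m + 1}" for m in avg.hard_labels],
                           index=means_df.index, name="phenotypic_group")
        sp_tab = crosstab(meta, labels, by="species")
        io.write_table(sp_tab.counts.reset_index(),
                       out / "crosstab_species.csv", meta_hdr)
        result = {"species": sp_tab}
        if "subpopulation" in meta.columns:
            sub_tab = crosstab(meta, labels, by="subpopulation")
            io.write_table(sub_tab.counts.reset_index(),
                           out / "crosstab_subpopulation.csv", meta_hdr)
            result["subpopulation"] = sub_tab
        if "osat_admixture_fraction" in meta.columns:
            adm, summary = admixture_partition(
                meta, threshold=config.admixture_threshold, groups=labels)
            io.write_table(adm.reset_index(), out / "admixture_labels.csv",
                           meta_hdr)
            result["admixture_labels"] = adm
            result["admixture_summary"] = summary
        midx = meta.set_index("accession_id") \
            if "accession_id" in meta.columns else meta
        chain = [("species",
                  midx["species"].reindex(labels.index)),
                 ("phenotypic_group", labels)]
        if "subpopulation" in midx.columns:
            chain.append(("subpopulation",
                          midx["subpopulation"].reindex(labels.index)))
        links = sankey_links(chain)
        io.write_table(links, out / "sankey_links.csv", meta_hdr)
        result["sankey"] = links
        return result

    io.write_json(provenance, out / "provenance.json")
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return bundle
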