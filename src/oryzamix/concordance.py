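"""Concordance between species designations, phenotypic groups and
genotypic subpopulations; admixture partitioning; core-accession selection;
Sankey link export.

Genebank species designations (*O. rufipogon*, *O. nivara*, *Oryza* spp. —
the uncertain *Oryza* spp. and *Oryza* hybr. designations are pooled),
phenotype-derived groups, and SNP-derived subpopulations (W1–W6) are three
partly concordant classifications of the same accessions. This module
cross-tabulates them, separates accessions heavily introgressed from
*O. sativa* (the ADM/OSAT class), selects "core" accessions on which all
three classifications agree, and emits the link tables behind Sankey plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "crosstab", "admixture_partition", "select_core", "sankey_links",
    "DEFAULT_CORE_MAP", "normalize_species",
]

#: default correspondence used by core selection: phenotypic group label ->
#: (species designation, compatible genotypic subpopulations)
DEFAULT_CORE_MAP = {
    "P1": ("O. rufipogon", {"W1", "W3", "W6"}),
    "P4": ("O. nivara", {"W2", "W5"}),
}

_SPECIES_MERGE = {"Oryza hybr.": "Oryza spp."}


class MetadataError(ValueError):
    """Metadata does not cover the assigned accessions."""


def normalize_species(species: pd.Series) -> pd.Series:
    """Pool the uncertain designations into a single *Oryza* spp. class."""
    return species.replace(_SPECIES_MERGE)


@dataclass
class CrosstabResult:
    counts: pd.DataFrame
    row_percent: pd.DataFrame
    unmatched: list


def _labels_series(assignment, index) -> pd.Series:
    if isinstance(assignment, pd.Series):
        return assignment
    labels = np.asarray(assignment)
    return pd.Series(labels, index=index)


def crosstab(metadata: pd.DataFrame, labels: pd.Series,
             by: str = "species") -> CrosstabResult:
    """Counts and row percentages of ``by`` (metadata column) x group.

    Accession IDs present in ``labels`` but absent from the metadata are
    reported in ``unmatched`` rather than silently dropped.
    """
    if by not in metadata.columns:
        raise KeyError(f"metadata lacks column {by!r}")
    meta = metadata.set_index("accession_id") \
        if "accession_id" in metadata.columns else metadata
    unmatched = [a for a in labels.index if a not in meta.index]
    common = [a for a in labels.index if a in meta.index]
    col = meta.loc[common, by]
    if by == "species":
        col = normalize_species(col)
    tab = pd.crosstab(labels.loc[common], col)
    pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
    return CrosstabResult(counts=tab, row_percent=pct, unmatched=unmatched)


def admixture_partition(metadata: pd.DataFrame, threshold: float = 0.5,
                        groups: pd.Series | None = None):
    """Label accessions with admixture fraction strictly above ``threshold``
    as ADM/OSAT; others keep their subpopulation label.

    Missing fractions are flagged "unknown". If ``groups`` (accession ->
    phenotypic group) is given, a per-group summary of mean admixture is
    returned as well.

    Returns
    -------
    labels : Series (accession_id -> subpopulation or "ADM/OSAT"/"unknown")
    summary : DataFrame or None
    """
    meta = metadata.set_index("accession_id") \
        if "accession_id" in metadata.columns else metadata
    frac = meta["osat_admixture_fraction"]
    sub = meta.get("subpopulation",
                   pd.Series("unknown", index=meta.index))
    out = sub.copy().astype(object)
    out[frac > threshold] = "ADM/OSAT"
    out[frac.isna()] = "unknown"
    out.name = "admixture_label"
    summary = None
    if groups is not None:
        joined = pd.DataFrame({"group": groups,
                               "fraction": frac.reindex(groups.index)})
        summary = joined.groupby("group")["fraction"] \
                        .agg(["mean", "median", "count"])
    return out, summary


def select_core(metadata: pd.DataFrame, groups: pd.Series,
                core_map: dict | None = None,
                admixture_max: float = 0.2,
                override_col: str = "species_override") -> dict:
    """Accessions on which species, phenotypic group and subpopulation agree.

    For each phenotypic group in ``core_map`` (default: P1 <-> O. rufipogon
    <-> {W1, W3, W6}; P4 <-> O. nivara <-> {W2, W5}), select accessions whose
    species designation and subpopulation both match AND whose *O. sativa*
    admixture fraction is strictly below ``admixture_max``. A
    ``species_override`` metadata column, when present and non-null,
    replaces the recorded species designation (e.g. for re-classified
    accessions).

    Returns a dict: species name -> sorted list of accession IDs.
    """
    core_map = core_map if core_map is not None else DEFAULT_CORE_MAP
    meta = metadata.set_index("accession_id") \
        if "accession_id" in metadata.columns else metadata
    species = normalize_species(meta["species"].copy())
    if override_col in meta.columns:
        ovr = meta[override_col]
        species = species.where(ovr.isna(), ovr)
    out = {}
    for g, (sp, subpops) in core_map.items():
        sel = []
        for acc in groups.index[groups == g]:
            if acc not in meta.index:
                continue
            frac = meta.at[acc, "osat_admixture_fraction"]
            if pd.isna(frac) or not frac < admixture_max:
                continue
            if species.get(acc) != sp:
                continue
            if meta.at[acc, "subpopulation"] not in subpops:
                continue
            sel.append(acc)
        out[sp] = sorted(sel)
    return out


def sankey_links(label_sets: list) -> pd.DataFrame:
    """Link table for a Sankey plot over an ordered chain of labelings.

    Parameters
    ----------
    label_sets : list of (stage_name, Series) pairs; all Series must share
        the same accession universe.

    Returns
    -------
    DataFrame with one row per (adjacent stage pair, source label, target
    label): columns source_stage, target_stage, source_label, target_label,
    count, accessions (comma-joined IDs). Counts are lossless: per
    transition they sum to the accession total.
    """
    if len(label_sets) < 2:
        raise ValueError("need at least two labelings")
    universe = set(label_sets[0][1].index)
    for name, s in label_sets[1:]:
        if set(s.index) != universe:
            raise ValueError(f"labeling {name!r} covers a different "
                             "accession set")
    rows = []
    for (name_a, a), (name_b, b) in zip(label_sets[:-1], label_sets[1:]):
        joined = pd.DataFrame({"src": a, "tgt": b.reindex(a.index)})
        for (src, tgt), grp in joined.groupby(["src", "tgt"], sort=True):
            rows.append({
                "source_stage": name_a, "target_stage": name_b,
                "source_label": src, "target_label": tgt,
                "count": len(grp),
                "accessions": ",".join(map(str, sorted(grp.index))),
            })
    return pd.DataFrame(rows)
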