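"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as TSV dosage matrices (rows = accessions, columns = SNPs)
or biallelic GT-only VCF; phenotypes as long-format CSV (accession_id, site,
trait, replicate, value); metadata and all stage outputs as single-header
UTF-8 CSV. Written tables carry a ``# key=value`` comment header with the
configuration hash and seeds, which pandas skips on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .relationship import RelationshipEmbedding

__all__ = [
    "read_genotypes_tsv", "write_genotypes_tsv",
    "read_genotypes_vcf", "write_minimal_vcf",
    "read_observations", "write_observations",
    "read_metadata", "write_table", "read_table",
    "write_embedding", "read_embedding",
]


def write_table(df: pd.DataFrame, path, header_meta: dict | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_genotypes_tsv(genotypes, accession_ids, path,
                        header_meta: dict | None = None) -> None:
    df = pd.DataFrame(np.asarray(genotypes),
                      index=accession_ids,
                      columns=[f"SNP{i:05d}" for i in
                               range(np.asarray(genotypes).shape[1])])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index_label="accession_id")


def read_genotypes_tsv(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.to_numpy(float), list(df.index)


def read_genotypes_vcf(path) -> tuple[np.ndarray, list]:
    """Read biallelic GT-only VCF into a dosage matrix (accessions x SNPs).

    Requires cyvcf2. Multi-allelic records are rejected; missing genotypes
    become NaN.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dosage = np.choose(gt.astype(int), [0.0, 1.0, np.nan, 2.0])
        cols.append(dosage)
    if not cols:
        raise ValueError("VCF contains no variants")
    return np.stack(cols, axis=1), samples


def write_minimal_vcf(genotypes, accession_ids, path,
                      chrom: str = "1") -> None:
    """Write a dosage matrix as a minimal biallelic GT-only VCF."""
    g = np.asarray(genotypes)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, accession_ids)) + "\n")
        for s in range(g.shape[1]):
            calls = "\t".join(
                gt_str.get(int(v), "./.") if np.isfinite(v) else "./."
                for v in g[:, s])
            fh.write(f"{chrom}\t{s + 1}\tSNP{s:05d}\tA\tT\t.\tPASS\t.\tGT\t"
                     f"{calls}\n")


def write_observations(obs: pd.DataFrame, path,
                       header_meta: dict | None = None) -> None:
    write_table(obs, path, header_meta=header_meta, index=False)


def read_observations(path) -> pd.DataFrame:
    df = read_table(path)
    need = {"accession_id", "trait", "replicate", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"observations CSV must have columns {sorted(need)}")
    return df


def read_metadata(path) -> pd.DataFrame:
    df = read_table(path)
    if "accession_id" not in df.columns:
        raise ValueError("metadata CSV must have an accession_id column")
    return df


def write_embedding(embedding: RelationshipEmbedding, g_path, u_path,
                    header_meta: dict | None = None) -> None:
    ids = (embedding.accession_ids
           or [f"ACC{i:04d}" for i in range(embedding.n_accessions)])
    Gdf = pd.DataFrame(embedding.G, index=ids, columns=ids)
    Udf = pd.DataFrame(embedding.U, index=ids,
                       columns=[f"EV{i:03d}" for i in
                                range(embedding.U.shape[1])])
    for df, path in ((Gdf, g_path), (Udf, u_path)):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in (header_meta or {}).items():
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, sep="\t", index_label="accession_id")


def read_embedding(g_path, u_path) -> RelationshipEmbedding:
    G = pd.read_csv(g_path, sep="\t", comment="#", index_col=0)
    U = pd.read_csv(u_path, sep="\t", comment="#", index_col=0)
    evals = (U.to_numpy() ** 2).sum(axis=0)  # columns scaled by sqrt(eig)
    return RelationshipEmbedding(G=G.to_numpy(), U=U.to_numpy(),
                                 eigenvalues=evals,
                                 kept_snp_count=-1,
                                 accession_ids=list(G.index))


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default),
                    encoding="utf-8")
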