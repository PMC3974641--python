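"""Readers and writers for the pipeline's interchange formats.

TSV is the tabular backbone; genotypes additionally round-trip through VCF
(GT fields, read via cyvcf2) and recombination blocks through BED-like TSV
(0-based half-open).  All readers validate schemas up front and normalize
coordinate conventions at the boundary.
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .array_quant import FEATURE_COLUMNS, ProteinMatrix
from .qtl import BlockPartition, GeneAnnotation, GenotypeMatrix

__all__ = [
    "read_vcf_dosages",
    "write_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_blocks_bed",
    "write_blocks_bed",
    "read_protein_tsv",
    "write_protein_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_feature_tsv",
    "write_feature_tsv",
    "read_gene_tsv",
    "write_gene_tsv",
    "read_qtl_tsv",
    "write_qtl_tsv",
    "file_sha256",
]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# VCF


def read_vcf_dosages(path, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Load GT-derived alternate-allele dosages from a VCF.

    Dosage = count of alternate alleles; missing GT -> NaN.  Multi-allelic
    records are skipped (default) or rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta, ids = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if skip_multiallelic:
                continue
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        g = rec.gt_types.astype(float)
        dos = np.where(g == 0, 0.0, np.where(g == 1, 1.0, np.where(g == 3, 2.0, np.nan)))
        rows.append(dos)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        ids.append(vid)
        meta.append(
            {"chrom": str(rec.CHROM), "pos": int(rec.POS), "ref": rec.REF, "alt": rec.ALT[0]}
        )
    variants = pd.DataFrame(meta, index=pd.Index(ids, name="variant_id"))
    dosages = pd.DataFrame(np.array(rows), index=variants.index, columns=samples)
    return GenotypeMatrix(variants, dosages)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write hard-call genotypes as a minimal VCFv4.2 with GT fields.

    Fractional dosages are rounded to the nearest hard call; NaN -> ./. .
    """
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = geno.variants["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individuals)
            + "\n"
        )
        for vid, var in geno.variants.iterrows():
            dos = geno.dosages.loc[vid]
            calls = [
                "./." if np.isnan(d) else gtmap[int(round(d))] for d in dos.to_numpy(dtype=float)
            ]
            fh.write(
                f"{var['chrom']}\t{int(var['pos'])}\t{vid}\t{var.get('ref', 'A')}\t"
                f"{var.get('alt', 'G')}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path, required: set[str], index_col=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str} if "chrom" in required else None)
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if index_col is not None:
        if df[index_col].duplicated().any():
            dup = df[index_col][df[index_col].duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicate id {dup!r}")
        df = df.set_index(index_col)
    return df


def write_genotype_tsv(geno: GenotypeMatrix, path) -> None:
    out = pd.concat([geno.variants, geno.dosages], axis=1)
    out.to_csv(path, sep="\t", index_label="variant_id")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = _read_tsv(path, {"variant_id", "chrom", "pos"}, index_col="variant_id")
    meta_cols = [c for c in ("chrom", "pos", "ref", "alt", "target_maf", "maf", "hwe_p") if c in df.columns]
    variants = df[meta_cols]
    dosages = df.drop(columns=meta_cols).astype(float)
    return GenotypeMatrix(variants, dosages)


def write_blocks_bed(blocks: BlockPartition, path) -> None:
    out = blocks.intervals[["chrom", "start", "end"]].copy()
    out["block_id"] = blocks.intervals.index
    out.to_csv(path, sep="\t", index=False)


def read_blocks_bed(path) -> BlockPartition:
    df = _read_tsv(path, {"chrom", "start", "end"})
    if "block_id" in df.columns:
        df = df.set_index("block_id")
    return BlockPartition(df)


def write_protein_tsv(prot: ProteinMatrix, path, provenance_path=None) -> None:
    flat = prot.values.copy()
    flat.columns = [f"{i}:{t}" for i, t in flat.columns]
    flat.to_csv(path, sep="\t", index_label="antibody")
    if provenance_path is not None and len(prot.provenance):
        prot.provenance.to_csv(provenance_path, sep="\t", index_label="antibody")


def read_protein_tsv(path, provenance_path=None) -> ProteinMatrix:
    df = _read_tsv(path, {"antibody"}, index_col="antibody")
    cols = []
    for c in df.columns:
        ind, _, thaw = c.rpartition(":")
        cols.append((ind, int(thaw) if thaw.isdigit() else thaw))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["individual", "thaw"])
    prov = pd.DataFrame()
    if provenance_path is not None and Path(provenance_path).exists():
        prov = _read_tsv(provenance_path, {"antibody"}, index_col="antibody")
    return ProteinMatrix(values=df.astype(float), provenance=prov)


def write_phenotype_tsv(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep="\t", index_label=phen.index.name or "individual")


def read_phenotype_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, {"individual"}, index_col="individual")


def write_feature_tsv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=False)


def read_feature_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, set(FEATURE_COLUMNS))


def write_gene_tsv(genes: GeneAnnotation, path) -> None:
    genes.genes.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_tsv(path) -> GeneAnnotation:
    return GeneAnnotation(_read_tsv(path, {"gene_id", "chrom", "tss", "tes"}, index_col="gene_id"))


QTL_COLUMNS = {"variant_id", "trait_id", "trait_class", "beta", "se", "p", "n"}


def write_qtl_tsv(qtl: pd.DataFrame, path) -> None:
    tab = qtl.reset_index() if qtl.index.name == "variant_id" else qtl
    tab.to_csv(path, sep="\t", index=False)


def read_qtl_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, QTL_COLUMNS)
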