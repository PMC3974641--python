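"""Genome-wide QTL mapping: genotype QC, trait transforms, single-variant scans.

The scan itself is ordinary simple linear regression of a (transformed) trait
on allelic dosage, applied variant-by-variant, followed by pruning to the most
significant variant per recombination block and cis/trans annotation of
molecular-trait hits.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "BlockPartition",
    "GeneAnnotation",
    "compute_maf",
    "hwe_exact_test",
    "qc_filter",
    "mean_impute",
    "inverse_normal_transform",
    "prepare_drug_trait",
    "gwas_linear",
    "best_per_block",
    "annotate_cis_trans",
]

CIS_WINDOW = 1_000_000  # bp flanking the gene body defining "cis"


@dataclass
class GenotypeMatrix:
    """Variant x individual dosage matrix with variant metadata.

    ``variants`` is indexed by variant_id with columns chrom, pos (1-based),
    and optionally ref/alt.  ``dosages`` shares that index; columns are
    individual ids; values are alternate-allele dosages in [0, 2], NaN for
    missing calls.
    """

    variants: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.variants.index.equals(self.dosages.index):
            raise ValueError("variants and dosages must share a variant index")
        if not self.variants.index.is_unique:
            raise ValueError("variant ids must be unique")
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def individuals(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> pd.Series:
        """Per-variant minor allele frequency over non-missing calls."""
        f = self.dosages.mean(axis=1, skipna=True) / 2.0
        return np.minimum(f, 1.0 - f).rename("maf")

    def subset(self, variant_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.variants.loc[variant_ids], self.dosages.loc[variant_ids])


@dataclass
class BlockPartition:
    """Ordered non-overlapping genomic intervals (0-based half-open).

    ``intervals`` has columns chrom, start, end and an index of block ids.
    Used as the LD-control unit: recombination blocks bounded by
    recombination-rate peaks.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end"}
        if not req.issubset(self.intervals.columns):
            raise ValueError(f"block table needs columns {sorted(req)}")
        for _, grp in self.intervals.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["end"] <= g["start"]).any():
                raise ValueError("blocks must have end > start")
            if (g["start"].values[1:] < g["end"].values[:-1]).any():
                raise ValueError("blocks overlap")

    @property
    def n_blocks(self) -> int:
        return len(self.intervals)

    def assign(self, variants: pd.DataFrame) -> pd.Series:
        """Map variants (columns chrom, pos; pos 1-based) to block ids.

        A variant at 1-based position p falls in [start, end) iff
        start <= p-1 < end.  Unmapped variants get NaN.
        """
        out = pd.Series(index=variants.index, dtype=object)
        for chrom, grp in self.intervals.groupby("chrom", sort=False):
            mask = variants["chrom"].astype(str) == str(chrom)
            if not mask.any():
                continue
            pos0 = variants.loc[mask, "pos"].to_numpy() - 1
            g = grp.sort_values("start")
            idx = np.searchsorted(g["start"].to_numpy(), pos0, side="right") - 1
            ok = (idx >= 0) & (pos0 < g["end"].to_numpy()[np.clip(idx, 0, None)])
            labels = np.full(len(pos0), None, dtype=object)
            labels[ok] = g.index.to_numpy()[idx[ok]]
            out.loc[mask] = labels
        return out


@dataclass
class GeneAnnotation:
    """Gene bodies (gene_id-indexed: chrom, tss, tes, strand) for cis calls."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "tss", "tes"}
        if not req.issubset(self.genes.columns):
            raise ValueError(f"gene table needs columns {sorted(req)}")
        if "strand" in self.genes.columns:
            bad = ~self.genes["strand"].isin(["+", "-"])
            if bad.any():
                raise ValueError("strand must be '+' or '-'")
        if (self.genes[["tss", "tes"]] <= 0).any().any():
            raise ValueError("tss/tes must be positive")


# ---------------------------------------------------------------------------
# genotype QC


def compute_maf(dosages) -> float:
    """Minor allele frequency from dosages in [0,2]; NaN entries are ignored."""
    arr = np.asarray(dosages, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        raise ValueError("cannot compute MAF: all dosages missing")
    f = obs.mean() / 2.0
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote configurations no more probable than the observed one
    (Wigginton-style enumeration).  Returns the exact p-value.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = int(n_AA + n_Aa + n_aa)
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = int(min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa))
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    if hets.size == 0:
        return 1.0
    # log P(h) ~ log [ n! / (nAA! nAa! naa!) * 2^h ] conditional normalization
    lf = [math.lgamma(k + 1) for k in range(2 * n + 1)]
    logp = np.empty(hets.size)
    for i, h in enumerate(hets):
        hom_rare = (n_minor - h) // 2
        hom_common = n - h - hom_rare
        logp[i] = h * math.log(2.0) - lf[h] - lf[hom_rare] - lf[hom_common]
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = int(n_Aa)
    p_obs = probs[np.searchsorted(hets, obs)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    geno: GenotypeMatrix, maf_min: float = 0.05, hwe_p_min: float = 0.001
) -> GenotypeMatrix:
    """Drop variants with MAF < maf_min or HWE exact p < hwe_p_min.

    Mirrors the standard pre-association genotype QC; survivor counts are
    recorded on the returned object's ``variants`` ("maf", "hwe_p" columns).
    """
    maf = geno.maf()
    dos = geno.dosages.to_numpy(dtype=float)
    hwe_p = np.ones(len(maf))
    rounded = np.rint(dos)
    hard = np.nanmax(np.abs(dos - rounded), axis=1) < 1e-6
    for i in range(dos.shape[0]):
        row = rounded[i][~np.isnan(rounded[i])].astype(int)
        if not hard[i] or row.size == 0:
            continue  # dosage-mode variants: HWE not testable, passes
        hwe_p[i] = hwe_exact_test(
            int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())
        )
    keep = (maf.to_numpy() >= maf_min) & (hwe_p >= hwe_p_min)
    out = geno.subset(geno.variants.index[keep])
    out.variants = out.variants.assign(maf=maf[keep], hwe_p=hwe_p[keep])
    return out


def mean_impute(dosages) -> np.ndarray:
    """Replace missing dosages with the observed mean (per variant)."""
    arr = np.asarray(dosages, dtype=float).copy()
    miss = np.isnan(arr)
    if arr.ndim == 1:
        if miss.all():
            raise ValueError("cannot impute: all dosages missing")
        arr[miss] = arr[~miss].mean()
        return arr
    if miss.all(axis=1).any():
        raise ValueError("cannot impute: some variant has all dosages missing")
    means = np.nanmean(arr, axis=1)
    rows, cols = np.where(miss)
    arr[rows, cols] = means[rows]
    return arr


# ---------------------------------------------------------------------------
# trait transforms


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^{-1}((rank - 0.5)/n) on midranks."""
    arr = np.asarray(values, dtype=float)
    if np.unique(arr).size < 3:
        raise ValueError("inverse normal transform needs >= 3 distinct values")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.5) / arr.size)


def prepare_drug_trait(values, log: bool = True) -> tuple[np.ndarray, float]:
    """Log-transform a drug phenotype and report its Shapiro-Wilk normality p.

    Drug-response readouts (growth inhibition, caspase activity) are
    right-skewed; the log brings them near normal.  A warning (not an error)
    is raised when the transformed values still deviate at p <= 0.001.
    """
    arr = np.asarray(values, dtype=float)
    if log:
        if (arr <= 0).any():
            bad = np.flatnonzero(arr <= 0)
            raise ValueError(f"nonpositive values at indices {bad.tolist()} cannot be log-transformed")
        arr = np.log(arr)
    sw_p = float(stats.shapiro(arr).pvalue)
    if sw_p <= 0.001:
        warnings.warn(
            f"trait deviates from normality after transform (Shapiro-Wilk p={sw_p:.2g})"
        )
    return arr, sw_p


# ---------------------------------------------------------------------------
# association scan


def gwas_linear(
    geno: GenotypeMatrix,
    trait: pd.Series,
    trait_id: str = "trait",
    trait_class: str = "protein",
) -> pd.DataFrame:
    """Single-variant linear regression of a trait on dosage, all variants.

    Returns a QTL table (one row per variant): beta, se, p (two-sided t),
    n.  Zero-variance variants yield NaN statistics.  Missing dosages should
    be imputed beforehand (see :func:`mean_impute`); any residual NaNs are
    mean-imputed here to keep the scan complete-case-free.
    """
    common = [i for i in geno.individuals if i in trait.index]
    if len(common) < 10:
        raise ValueError("trait and genotypes share fewer than 10 individuals")
    y = trait.loc[common].to_numpy(dtype=float)
    X = geno.dosages[common].to_numpy(dtype=float)
    if np.isnan(X).any():
        X = mean_impute(X)
    n = len(common)
    xm = X.mean(axis=1, keepdims=True)
    xc = X - xm
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=1)
    sxy = xc @ yc
    syy = float((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    zero = sxx <= 0
    beta[zero] = np.nan
    se[zero] = np.nan
    p[zero] = np.nan
    return pd.DataFrame(
        {
            "variant_id": geno.variants.index,
            "trait_id": trait_id,
            "trait_class": trait_class,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    ).set_index("variant_id")


def gwas_scan(
    geno: GenotypeMatrix, traits: pd.DataFrame, trait_class: str = "protein"
) -> pd.DataFrame:
    """Run :func:`gwas_linear` for every trait column; concatenated QTL table."""
    parts = [
        gwas_linear(geno, traits[c], trait_id=c, trait_class=trait_class)
        for c in traits.columns
    ]
    return pd.concat(parts).reset_index()


def best_per_block(qtl: pd.DataFrame, geno: GenotypeMatrix, blocks: BlockPartition) -> pd.DataFrame:
    """Keep the most significant variant per (recombination block, trait).

    Ties on p are broken by smaller genomic position, then lexicographic
    variant id, so pruning is deterministic.
    """
    tab = qtl.reset_index() if qtl.index.name == "variant_id" else qtl.copy()
    block_of = blocks.assign(geno.variants)
    missing = [v for v in tab["variant_id"].unique() if pd.isna(block_of.get(v))]
    if missing:
        raise ValueError(f"variants not mapped to any block: {missing[:5]}")
    tab = tab.assign(
        _block=tab["variant_id"].map(block_of),
        _pos=tab["variant_id"].map(geno.variants["pos"]),
    )
    tab = tab.sort_values(["p", "_pos", "variant_id"], kind="mergesort")
    out = tab.groupby(["_block", "trait_id"], sort=False).head(1)
    return out.drop(columns=["_block", "_pos"]).reset_index(drop=True)


def annotate_cis_trans(
    qtl: pd.DataFrame,
    geno: GenotypeMatrix,
    genes: GeneAnnotation,
    trait_gene: pd.Series | dict,
    window: int = CIS_WINDOW,
    strand_aware: bool = False,
) -> pd.DataFrame:
    """Label molecular-trait QTL rows cis or trans.

    A variant is cis for its trait's gene iff it lies on the same chromosome
    within ``window`` bp of the gene body.  Default is strand-agnostic
    (window around [min(tss,tes), max(tss,tes)]); strand-aware mode extends
    the window upstream of the TSS and downstream of the TES per strand.
    Traits without a gene mapping are labeled "unknown" with a warning.
    """
    trait_gene = pd.Series(trait_gene)
    tab = qtl.reset_index() if qtl.index.name == "variant_id" else qtl.copy()
    labels = []
    warned = set()
    for _, row in tab.iterrows():
        gene_id = trait_gene.get(row["trait_id"])
        if gene_id is None or gene_id not in genes.genes.index:
            if row["trait_id"] not in warned:
                warnings.warn(f"trait {row['trait_id']} has no gene mapping")
                warned.add(row["trait_id"])
            labels.append("unknown")
            continue
        g = genes.genes.loc[gene_id]
        var = geno.variants.loc[row["variant_id"]]
        if str(var["chrom"]) != str(g["chrom"]):
            labels.append("trans")
            continue
        if strand_aware:
            # tss/tes taken in transcription orientation: window runs from
            # 1 Mb upstream of the TSS to 1 Mb downstream of the TES
            if g.get("strand", "+") == "-":
                lo, hi = g["tes"] - window, g["tss"] + window
            else:
                lo, hi = g["tss"] - window, g["tes"] + window
        else:
            lo = min(g["tss"], g["tes"]) - window
            hi = max(g["tss"], g["tes"]) + window
        labels.append("cis" if lo <= var["pos"] <= hi else "trans")
    return tab.assign(cis_trans=labels)
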