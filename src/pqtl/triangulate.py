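"""Triangulation: drug-associated SNP -> target protein -> drug phenotype.

A variant implicates a protein in drug response when three links hold at
once: the variant associates with the drug phenotype (dQTL p < 1e-3), the
variant is a pQTL for the protein (p < 1e-4), and the protein's abundance
itself correlates with the drug phenotype (p <= 0.05).  Boundary semantics
follow the printed operators exactly: strict for the two QTL thresholds,
inclusive for the protein-drug correlation.  Also provides the 2x2 Fisher
overlap machinery used to ask whether trans-pQTLs are enriched for
cis-eQTLs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TriangulationResult",
    "OverlapTable2x2",
    "triangulate",
    "cross_phenotype_overlap",
    "fisher_overlap",
    "overlap_percent",
]


@dataclass
class TriangulationResult:
    drug: str
    phenotype: str  # "apoptosis" | "cytotoxicity"
    triplets: pd.DataFrame  # variant_id, antibody, dqtl_p, pqtl_p, protein_drug_p
    implicated_snps: int = field(init=False)
    implicated_proteins: int = field(init=False)

    def __post_init__(self):
        self.implicated_snps = self.triplets["variant_id"].nunique()
        self.implicated_proteins = self.triplets["antibody"].nunique()

    @property
    def protein_set(self) -> set:
        return set(self.triplets["antibody"])


@dataclass(frozen=True)
class OverlapTable2x2:
    """Counts a, b, c, d of a 2x2 class-of-interest x condition table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


def triangulate(
    drug_qtl: pd.DataFrame,
    protein_qtl: pd.DataFrame,
    assoc: pd.DataFrame,
    drug: str,
    phenotype: str,
    dqtl_p: float = 1e-3,
    pqtl_p: float = 1e-4,
    prot_p: float = 0.05,
) -> TriangulationResult:
    """Intersect dQTLs with pQTLs and filter to drug-correlated target proteins.

    ``drug_qtl``: QTL table for the phenotype ``{drug}_{phenotype}``;
    ``protein_qtl``: QTL table with protein trait ids (= antibody ids);
    ``assoc``: protein-drug association table (columns antibody, phenotype,
    p).  Thresholds: dQTL strict <, pQTL strict <, protein-drug inclusive <=.
    """
    req = {
        "drug_qtl": (drug_qtl, {"variant_id", "p"}),
        "protein_qtl": (protein_qtl, {"variant_id", "trait_id", "p"}),
        "assoc": (assoc, {"antibody", "phenotype", "p"}),
    }
    for name, (tab, cols) in req.items():
        if tab is None:
            raise ValueError(f"missing table: {name}")
        if not cols.issubset(tab.columns):
            raise ValueError(f"table {name} lacks columns {sorted(cols - set(tab.columns))}")

    phenotype_id = f"{drug}_{phenotype}"
    dq = drug_qtl.loc[drug_qtl["p"] < dqtl_p, ["variant_id", "p"]].rename(
        columns={"p": "dqtl_p"}
    )
    pq = protein_qtl.loc[protein_qtl["p"] < pqtl_p, ["variant_id", "trait_id", "p"]].rename(
        columns={"trait_id": "antibody", "p": "pqtl_p"}
    )
    pa = assoc.loc[
        (assoc["phenotype"] == phenotype_id) & (assoc["p"] <= prot_p), ["antibody", "p"]
    ].rename(columns={"p": "protein_drug_p"})

    trip = dq.merge(pq, on="variant_id").merge(pa, on="antibody")
    trip = trip[["variant_id", "antibody", "dqtl_p", "pqtl_p", "protein_drug_p"]]
    return TriangulationResult(drug=drug, phenotype=phenotype, triplets=trip.reset_index(drop=True))


def cross_phenotype_overlap(
    result_apoptosis: TriangulationResult, result_cytotoxicity: TriangulationResult
) -> set:
    """Proteins implicated through both the apoptosis and cytotoxicity scans."""
    if result_apoptosis.drug != result_cytotoxicity.drug:
        raise ValueError(
            f"drug mismatch: {result_apoptosis.drug} vs {result_cytotoxicity.drug}"
        )
    return result_apoptosis.protein_set & result_cytotoxicity.protein_set


def fisher_overlap(table: OverlapTable2x2) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for a 2x2 overlap table.

    Two-sided p sums all tables (with the observed margins) whose
    hypergeometric probability does not exceed the observed table's.
    """
    if min(table.a + table.b, table.c + table.d, table.a + table.c, table.b + table.d) == 0:
        raise ValueError("zero margin: odds ratio undefined")
    odds, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(odds), float(p)


def overlap_percent(overlap_count: int, total_count: int, ndigits: int = 1) -> float:
    """Percentage of a count over a total, rounded to the printed precision."""
    if total_count <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * overlap_count / total_count, ndigits)
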