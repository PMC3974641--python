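#!/usr/bin/env python
"""Test whether drug-associated variants are enriched for pQTLs.

For each drug phenotype, selects dQTLs at p<1e-3 (best variant per
recombination block), draws 200 MAF-matched random variant sets, and ranks
the observed dQTL-pQTL overlap within the null distribution.  Phenotypes
whose planted chain injects true pQTL signal should enrich; the others
provide in-run negative controls.
"""
import json
import warnings
from pathlib import Path

import pandas as pd

from pqtl import io as pio
from pqtl.enrichment import run_enrichment
from pqtl.pipeline import PipelineConfig
from pqtl.qtl import mean_impute, qc_filter

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "enrichment"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_yaml(ROOT / "analysis" / "config.yaml")
    geno = pio.read_genotype_tsv(ROOT / "results" / "cohort" / "genotypes.tsv")
    blocks = pio.read_blocks_bed(ROOT / "results" / "cohort" / "blocks.bed")
    geno = qc_filter(geno)
    geno.dosages = pd.DataFrame(
        mean_impute(geno.dosages.to_numpy(float)),
        index=geno.dosages.index, columns=geno.dosages.columns,
    )
    pqtl = pio.read_qtl_tsv(ROOT / "results" / "qtl" / "pqtl.tsv")
    dqtl = pio.read_qtl_tsv(ROOT / "results" / "qtl" / "dqtl.tsv")

    summary = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ph in sorted(dqtl["trait_id"].unique()):
            res = run_enrichment(
                dqtl[dqtl["trait_id"] == ph], pqtl, geno, blocks,
                phenotype_id=ph, n_perm=cfg.n_perm, seed=cfg.seed,
            )
            res.to_json(OUT / f"enrichment_{ph}.json")
            res.to_tsv(OUT / f"enrichment_{ph}.tsv")
            summary[ph] = {"observed": res.observed_overlap,
                           "empirical_p": res.empirical_p}
            flag = " <-- enriched" if res.empirical_p < 0.05 else ""
            print(f"{ph}: observed dQTL-pQTL overlap {res.observed_overlap}, "
                  f"empirical p = {res.empirical_p:.4g}{flag}")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
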