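#!/usr/bin/env python
"""Generate the synthetic study cohort with planted truth.

Emulates the study design: 50 cell lines x 3 thaws, 60 antibodies, 2,000
variants in 200 recombination blocks, with two planted pQTLs (one cis, one
trans) whose target proteins also drive a drug phenotype, so the full
variant -> protein -> drug chain exists by construction.  Writes genotypes
(TSV + VCF), blocks (BED), the true protein matrix, drug phenotypes, spot
features and the truth record under results/cohort/.
"""
from pathlib import Path

from pqtl import io as pio
from pqtl.pipeline import PipelineConfig
from pqtl.simulate import (
    simulate_array_features,
    simulate_drug_phenotypes,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_protein_matrix,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "cohort"


def main():
    cfg = PipelineConfig.from_yaml(ROOT / "analysis" / "config.yaml").simulation_config()
    OUT.mkdir(parents=True, exist_ok=True)

    geno, blocks = simulate_genotypes(cfg)
    prot, truth = simulate_protein_matrix(cfg, geno)
    phen = simulate_drug_phenotypes(cfg, prot)
    feats = simulate_array_features(cfg, prot)
    genes, gene_of = simulate_gene_annotation(cfg, geno)

    pio.write_genotype_tsv(geno, OUT / "genotypes.tsv")
    pio.write_vcf(geno, OUT / "genotypes.vcf")
    pio.write_blocks_bed(blocks, OUT / "blocks.bed")
    pio.write_protein_tsv(prot, OUT / "proteins_true.tsv")
    pio.write_phenotype_tsv(phen, OUT / "phenotypes.tsv")
    pio.write_feature_tsv(feats, OUT / "features.tsv")
    pio.write_gene_tsv(genes, OUT / "genes.tsv")
    gene_of.to_csv(OUT / "antibody_gene_map.tsv", sep="\t", header=True,
                   index_label="antibody")
    truth.to_json(OUT / "truth.json")

    print(f"cohort: {cfg.n_individuals} individuals x {cfg.n_thaws} thaws, "
          f"{cfg.n_variants} variants in {cfg.n_blocks} blocks, "
          f"{cfg.n_antibodies} antibodies")
    print(f"planted pQTLs: {[(p.variant_id, p.antibody_id, p.kind) for p in truth.pqtl_map]}")
    print(f"spot features written: {len(feats)} rows -> {OUT}")


if __name__ == "__main__":
    main()
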