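# Demo-scale study configuration shared by the numbered analysis scripts.
# Thresholds are the analysis defaults: dQTL p<1e-3, pQTL p<1e-4,
# protein-drug p<=0.05, MAF>=0.05, HWE exact p>=0.001, S/N>=3.
seed: 20240301
n_perm: 200
cluster_n_perm: 200
simulation:
  n_individuals: 50
  n_thaws: 3
  n_variants: 2000
  n_blocks: 200
  n_antibodies: 60
  thaw_variance_fraction: 0.0529
  planted_pqtls:
    - {variant_id: var000100, antibody_id: AB0005, beta: 2.0, kind: cis}
    - {variant_id: var001500, antibody_id: AB0020, beta: 2.0, kind: trans}
  planted_drug_effects:
    - {antibody_id: AB0005, phenotype_id: paclitaxel_apoptosis, beta: 1.2}
    - {antibody_id: AB0020, phenotype_id: cisplatin_cytotoxicity, beta: 1.2}
  planted_growth_effects:
    - [AB0011, 0.7]
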