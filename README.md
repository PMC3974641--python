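# pqtl

Protein quantitative trait locus (pQTL) mapping for cell-line
pharmacogenomics: from antibody-array spot intensities to triangulated
variant → protein → drug-response relationships.

## The problem

Most functional annotation of GWAS hits runs through mRNA (eQTLs), but
mRNA and protein levels correlate poorly, so variants acting on protein
abundance are missed. The design this package implements measures
steady-state levels of a few hundred signaling/transcription-factor
proteins across a panel of lymphoblastoid cell lines (several independent
*thaws* per line as biological replicates, quantified on reverse-phase
protein arrays and micro-western arrays), together with per-line drug
phenotypes (apoptosis = caspase 3/7 activation, and cytotoxicity =
short-term growth inhibition, for each drug). The pipeline then:

1. **Quantifies arrays** — feature QC (background-subtracted intensity ≥ 0,
   S/N ≥ 3), log2 quantile normalization across the arrays of a print,
   micro-western batch alignment, per-sample load correction
   *eᵢₚ = μᵢₚ − λᵢ* with *λᵢ = medianₚ(μᵢₚ)*, replicate aggregation with
   platform selection by median intensity, and antibody decile filtering
   (bottom intensity decile ∪ top technical-CV decile removed).
2. **Associates proteins with drug response** by a replicate-aware mixed
   model, `protein ~ phenotype + (1 | individual)`, fitted by ML with a
   likelihood-ratio test on the phenotype coefficient and Storey q-values
   across antibodies. Thaws with conflicting trends attenuate significance
   relative to averaging — the reason for measuring replicates at all.
3. **Maps QTLs** — genotype QC (MAF ≥ 0.05, Hardy-Weinberg exact p ≥ 0.001),
   mean dosage imputation, inverse normal transform of protein traits,
   per-variant linear regression genome-wide, pruning to the most
   significant variant per recombination block, cis/trans annotation
   (±1 Mb around the gene body).
4. **Tests enrichment** of drug-associated variants (dQTLs, p < 10⁻³,
   best-per-block) in pQTLs (p < 10⁻⁴) against 1,000 random variant sets
   matched to the dQTL minor-allele-frequency histogram; empirical
   p = (r+1)/(n+1).
5. **Triangulates**: a variant implicates a protein in drug response when
   dQTL p < 10⁻³, pQTL p < 10⁻⁴, and the protein-drug correlation has
   p ≤ 0.05 — boundary semantics exactly as printed.
6. **Clusters** proteins by their standardized drug-phenotype coefficients
   (apoptosis columns sign-inverted) with Ward/Euclidean linkage, choosing
   the number of clusters by permuting each coefficient column
   independently and comparing merge heights against the permutation
   envelope.

Because the original protein data carry no public accession, a first-class
synthetic-cohort generator (`pqtl.simulate`) reproduces the study design —
68 lines × 3 thaws × 441 antibodies by default, a thaw variance component
of 5.29% of non-genetic variance, apoptosis/cytotoxicity r² targets of
0.35 (paclitaxel-like) and 0.04 (cisplatin-like), block-copula LD — with
every planted effect recorded, so each stage is tested by parameter
recovery rather than against unavailable data.

## Worked example

The numbered scripts under `analysis/` run the whole study at demo scale
(50 lines × 3 thaws, 2,000 variants in 200 blocks, 60 antibodies, two
planted variant → protein → drug chains; see `analysis/config.yaml`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quantify_arrays.py
...
python analysis/07_cluster_coefficients.py
```

Output of a full run (abridged):

```
feature QC: 31050 spots -> 28817 (2233 excluded)
antibodies: 60 assayed -> 51 retained after decile filter (platforms kept: {'MWA': 33, 'RPPA': 27})
rank agreement with planted truth: median Spearman rho = 0.963 (min 0.941)
mixed effect: 16/204 associations at p<0.05, 3 at q<=0.20
genotype QC: 2000 variants -> 1961 (MAF >= 0.05 and HWE exact p >= 0.001)
pQTL scan: 100011 tests, 16 at p<1e-4 (4 cis / 12 trans)
planted cis pQTL var000100 -> AB0005: p = 1.74e-08, labeled cis
planted trans pQTL var001500 -> AB0020: p = 3.76e-07, labeled trans
cisplatin_cytotoxicity: observed dQTL-pQTL overlap 1, empirical p = 0.01493 <-- enriched
paclitaxel_apoptosis: observed dQTL-pQTL overlap 1, empirical p = 0.0398 <-- enriched
planted chains recovered as triplets: 2/2
permutation test (200 column permutations): k = 1, p = 1
```

Reading this: quantification recovers the planted expression matrix to
rank correlation ≳ 0.95 per antibody; both planted pQTLs reach genome-wide
significance with the correct cis/trans label; the only two phenotypes
showing pQTL enrichment are exactly the two carrying a planted chain; both
chains survive triangulation; and with effects planted on single proteins
the cluster-count test correctly reports no group structure (k = 1).

The same machinery is available as a CLI (`pqtl simulate|quantify|assoc|
qtl|enrich|triangulate|cluster|run`) for file-based use.

## Layout

```
src/pqtl/        library: simulate, array_quant, assoc, qtl, enrichment,
                 triangulate, cluster, io, pipeline, cli
analysis/        numbered study drivers (write under results/)
tests/           pytest suite (unit, property, end-to-end)
scripts/         acceptance.py
docs/methods.md  modeling and design notes
```
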