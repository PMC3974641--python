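# Methods and design notes

## Array quantification

Spot features carry `signal`, `background` and a per-spot noise scale.
Feature QC removes spots with background-subtracted intensity < 0 or
signal-to-noise (corrected intensity / noise SD) below 3; the numeric
threshold is the operative rule, applied symmetrically on both platforms.

Corrected intensities are averaged over technical replicate spots per
(array, sample), then **log2 quantile normalized** across the arrays of a
print: each array's values are mapped rank-for-rank onto the mean of the
sorted log2 columns, ties receiving the mean target of their tied ranks.
This equalizes antibody hybridization-efficiency differences; it
deliberately forces identical marginal distributions, so absolute
between-antibody contrasts are not interpretable downstream — only
between-sample contrasts within an antibody are.

Sample-load correction implements relative expression
`e(j,p) = mu(j,p) - lambda(j)` with `lambda(j) = median_p mu(j,p)` over
the arrays of a print (per platform here; the print-run grouping is a
parameter). Micro-western batches are aligned by shifting each batch's
median to the global median before load correction. Nonpositive corrected
intensities are set missing, never clamped, so they cannot leak into the
log domain.

Replicates within a platform are averaged; an antibody measured on both
platforms keeps the one with the higher median raw corrected intensity
(ties prefer the single-band reverse-phase platform). The decile filter
drops antibodies in the bottom decile of median corrected intensity or the
top decile of technical CV (CV computed on unlogged intensities across
technical replicates), per platform, with linear-interpolation percentiles
and inclusive (conservative) boundary handling; platforms with fewer than
10 antibodies skip the filter with a warning.

## Replicate-aware association model

Protein abundance is measured once per (individual, thaw); the thaw is the
biological replicate. The association of a protein with a per-individual
drug phenotype is

    value_it = a + b * phenotype_i + u_i + e_it,   u_i ~ N(0, s2_u)

fitted by maximum likelihood (statsmodels MixedLM); the p-value for `b`
is a likelihood-ratio test of the full against the intercept-only model
(chi-square, 1 df). The upper-bound-degrees-of-freedom F approximation
some R convenience wrappers use is avoided as non-portable; the LRT is
asymptotically equivalent and measured here to be well calibrated at the
study's sample size (type-I rate 0.0505 over 2,000 null fits at alpha
0.05; p-values uniform, KS p = 0.71). Protein values are z-scored before
fitting so coefficients are in protein-SD units per phenotype unit.
Per-individual phenotypes are replicated across that individual's thaw
rows; a per-thaw phenotype series indexed by (individual, thaw) is also
accepted. Degenerate cases: a zero-variance phenotype is an error; all
singleton groups fall back to OLS with a warning; zero within-individual
variance reduces exactly to OLS on individual means.

Storey q-values estimate pi0 from pi0(lambda) = #{p > lambda} / (m (1 -
lambda)) on lambda = 0.05 ... 0.95, smoothed with a least-squares cubic
evaluated at the largest lambda and capped at 1; below 100 tests the
estimate is unstable and pi0 = 1 is used, which reduces the procedure to
Benjamini-Hochberg exactly (used as the test oracle).

## Variance decomposition

Nested components (individual / thaw-within-individual /
culture-within-thaw / residual) are estimated by balanced nested-ANOVA
method of moments — expected mean squares solved top-down and truncated at
zero. REML variance components were tried and rejected: the statsmodels
optimizer fails to converge at the boundary, assigning substantial
variance to null grouping levels. A level whose units carry a single
measurement each is confounded with the level below it; the estimator
then attributes within-individual variance to the thaw component when
thaws are unreplicated (the production design: thaw is the replicate
unit) and reports zero for singleton-culture designs, where sub-thaw
scatter is residual by construction.

## Synthetic cohort

The generator plants known structure at the scale of the study design and
records all of it (`SyntheticTruth`):

- **Genotypes**: hard calls in {0,1,2} under Hardy-Weinberg at a target
  MAF drawn uniform on [0.05, 0.5]; LD by block copula — each
  recombination block shares a latent Gaussian factor per haplotype
  (within-block latent correlation 0.8 by default), alleles are quantile
  thresholds of the latent value. Blocks tile chromosomes 1–22
  round-robin, variants 5 kb apart; the block table is 0-based half-open.
  Optional missingness and a continuous dosage mode (clipped Gaussian
  perturbation of the hard call). This preserves the block structure the
  enrichment test needs, not human allele-frequency or recombination
  realism.
- **Proteins**: value = sum(planted beta x dosage) + b_i + u_it (+ e),
  with the non-genetic variance split as individual / thaw / sub-thaw
  residual. The thaw fraction defaults to 0.0529 — the pilot-design
  estimate of between-thaw variance — and the sub-thaw residual defaults
  to 0, consistent with culture-level variance being negligible; with one
  measurement per thaw a nonzero sub-thaw residual would be unrealizable
  anyway.
- **Drug phenotypes**: per-individual; phenotype = sum(planted beta x
  z-scored individual-mean protein) + noise. Within a drug the apoptosis
  and cytotoxicity residuals are drawn jointly with the correlation solved
  so the realized squared correlation meets the target (defaults 0.35
  paclitaxel-like, 0.04 cisplatin-like); the planted correlation is
  negative, matching the inverse relation between growth inhibition and
  caspase activation. If planted effects make the target unreachable the
  correlation is clipped with a warning. Phenotypes are emitted on the
  linear latent scale; the log-transform path (`prepare_drug_trait`, with
  its Shapiro-Wilk gate at p = 0.001) is exercised on lognormal inputs.
- **Array features**: one array per antibody (4 technical spots on RPPA,
  3 on MWA, ~24 antibodies per micro-western batch), spot intensity =
  500 x 2^(true value + antibody abundance + sample load + array shift
  [+ batch offset]) + background + Gaussian spot noise; configurable
  fractions of spots are forced to fail each QC rule. At default noise the
  quantification round trip achieves per-antibody Spearman rho > 0.9
  against the planted matrix.
- **siRNA**: lognormal response with random line and experiment
  intercepts and a multiplicative knockdown effect; the knockdown model
  (log response, crossed random intercepts, LRT) mirrors the association
  machinery.

What the generator does **not** emulate: population structure, realistic
allele-frequency spectra, antibody cross-reactivity, shared-pathway
protein correlation, or drug dose-response curves. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to those real-data complications.

## Enrichment null

MAF bins are 0.02 wide over [0, 0.5] (the bin width is not dictated by
anything in the design; 0.02 resolves the MAF range without emptying
bins at desk scale). Null sets are sampled without replacement within a
set, per bin, from post-QC variants; dQTL variants stay eligible —
excluding them would bias the null upward. Block control (best variant
per recombination block) applies to the dQTL set; a symmetry flag can
apply it to null sets too (off by default). The empirical p-value uses
the (r+1)/(n+1) convention, so 1/1001 is the floor at 1,000 permutations.

A calibration subtlety: the overlap count is an integer, so its
permutation p-value is discrete and superuniform when the target-QTL set
is sparse (few attainable overlap values). Distribution-shape checks of
the empirical p against the continuous uniform are therefore run with a
dense target set, where the statistic takes ~100 distinct values;
sparse-target behaviour is conservative, not anticonservative.

## Cluster-count permutation test

Ward linkage (Ward.D2 update on Euclidean distances) on the antibody x
phenotype matrix of standardized coefficients, apoptosis columns
multiplied by -1 first so all columns share the "higher level = more
resistant" direction. The null shuffles each column independently across
rows — destroying row structure, preserving column marginals — and two
decision rules are provided:

- `max_height` (default): cut the observed tree at the lowest merge
  height exceeding the maximum height over all permutations; k is the
  cluster count at that cut, p = (1 + #{perm max >= cut}) / (1 + n_perm).
- `per_merge`: compare each merge height against the permutation maximum
  at the same merge index, counting significant merges contiguously from
  the top of the tree.

The two rules differ in resolution, not calibration (both give k = 1 on
noise in >= 95% of seeds). Because column shuffles preserve column
marginals, the global max-height envelope is dominated by the largest
single-column structure; with only four phenotype columns it cannot
resolve five or more well-separated clusters, whose smallest between-
cluster merge sits below the envelope. The per-merge rule compares each
merge against its own permutation stratum and recovers planted k in
{2, 3, 5} essentially always at per-column separations of ~5 noise SD.
Recovery benchmarks use regular-simplex cluster centers under a random
rotation: structure confined to one column is invisible to a
column-shuffle null at any separation, so rotation (spreading separation
across columns) is what makes the planted k detectable at all.

## Numerical and interface conventions

- HWE exact test: conditional on allele counts, heterozygote
  configurations no more probable than the observed one are summed;
  log-factorial arithmetic with a relative tie tolerance of 1e-12;
  verified exhaustively against an exact-rational enumeration for all
  tables with n <= 50.
- GWAS regression: closed-form simple-regression algebra per variant
  (two-sided t), agreeing with the correlation-test form to 1e-10;
  zero-variance variants yield NaN rows rather than errors.
- best-per-block ties: smaller p, then smaller position, then variant id.
- Coordinates: VCF/variant positions 1-based; block intervals 0-based
  half-open; conversion only at the assignment boundary.
- cis window: +-1 Mb around the gene body, strand-agnostic by default
  (a strand-aware mode extends upstream of TSS / downstream of TES).
- Thresholds: dQTL p < 1e-3 and pQTL p < 1e-4 strict; protein-drug
  p <= 0.05 inclusive; MAF and HWE cuts inclusive on the keep side.
- All randomness flows from explicit integer seeds; generator stages use
  independent seeded substreams, so outputs are byte-identical across
  runs with the same configuration.

## Problem sizes

The demo cohort (analysis/, the end-to-end smoke test) uses 50 lines x 3
thaws, 2,000 variants in 200 blocks, 60 antibodies and 200 permutations —
chosen so the full chain (including ~250 mixed-model fits) completes in a
few minutes while every planted effect is still comfortably detectable.
Calibration checks use the sizes their statistics need: 2,000 null
mixed-model fits for the type-I rate, 200 repetitions x 200 permutations
for enrichment calibration, 100 seeds per planted k for cluster recovery,
and the exhaustive n <= 50 sweep for the HWE test.

## Known limitations

- The load effect lambda_j is a median over the arrays of a print; for
  narrow antibody panels its estimation noise bounds round-trip fidelity
  (visible in the noiseless round-trip test, which uses a 200-antibody
  panel).
- The mixed model fits one random intercept per individual; with one
  measurement per (individual, thaw), thaw and measurement noise are
  inseparable by design, and the variance decomposition documents that
  attribution explicitly.
- Empirical enrichment p-values are bounded below by 1/(n_perm+1) and are
  discrete; treat "p < 0.001" at 1,000 permutations as an exceedance
  statement, not a density estimate.
- The eQTL side of triangulation accepts a precomputed association table
  in the same schema; no transcript quantification is performed.
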