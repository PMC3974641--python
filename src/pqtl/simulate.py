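"""Synthetic cohort generator with planted truth.

Emulates the study design the pipeline targets: a panel of lymphoblastoid
cell lines (default 68 individuals) with three independent thaws per
individual, a few hundred antibody-level protein measurements, genotypes
organised into recombination blocks with within-block LD, drug phenotypes
(apoptosis and cytotoxicity per drug) with protein-mediated effects, spot
level array features, and siRNA knockdown experiments.  Every planted
effect is recorded in a :class:`SyntheticTruth` object so downstream stages
can be tested for parameter recovery.

Noise model for protein values: for antibody a, individual i, thaw t,

    x[a,i,t] = sum_planted beta * dosage(v,i) + b_i + u_it (+ e_itc)

where b is a between-individual biological effect, u a thaw-within-
individual random intercept and e a sub-thaw (culture/technical) residual.
The three components split the non-genetic variance (noise_sd^2) according
to ``thaw_variance_fraction`` (default 0.0529, the pilot-study estimate of
between-thaw variance) and ``residual_variance_fraction`` (default 0: with
one measurement per thaw, sub-thaw residual is not separately realised,
matching the pilot finding that culture-level variance is negligible).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .array_quant import ProteinMatrix
from .qtl import BlockPartition, GeneAnnotation, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "PlantedPQTL",
    "PlantedDrugEffect",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_protein_matrix",
    "simulate_drug_phenotypes",
    "simulate_array_features",
    "simulate_gene_annotation",
    "simulate_coefficient_blocks",
    "simulate_sirna_experiment",
]

DEFAULT_DRUG_R2 = {"paclitaxel": 0.35, "cisplatin": 0.04}
ENDPOINTS = ("apoptosis", "cytotoxicity")


@dataclass(frozen=True)
class PlantedPQTL:
    variant_id: str
    antibody_id: str
    beta: float  # protein SD units per alternate allele
    kind: str = "cis"  # cis | trans

    def __post_init__(self):
        if self.kind not in ("cis", "trans"):
            raise ValueError("planted pQTL kind must be 'cis' or 'trans'")


@dataclass(frozen=True)
class PlantedDrugEffect:
    antibody_id: str
    phenotype_id: str  # e.g. "paclitaxel_apoptosis"
    beta: float


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed is mandatory."""

    n_individuals: int = 68
    n_thaws: int = 3
    n_variants: int = 2000
    n_blocks: int = 200
    n_antibodies: int = 441
    n_rppa_antibodies: int | None = None  # default: 198/441 of the panel
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_ld: float = 0.8  # latent within-block haplotype correlation
    thaw_variance_fraction: float = 0.0529
    residual_variance_fraction: float = 0.0
    n_cultures: int = 1  # sub-thaw replicates (pilot-style designs)
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    dosage_mode: bool = False
    dosage_noise_sd: float = 0.1
    planted_pqtls: tuple[PlantedPQTL, ...] = ()
    planted_drug_effects: tuple[PlantedDrugEffect, ...] = ()
    planted_growth_effects: tuple[tuple[str, float], ...] = ()
    apoptosis_cytotox_r2: dict = field(default_factory=lambda: dict(DEFAULT_DRUG_R2))
    drug_noise_sd: float = 1.0
    per_thaw_phenotypes: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("n_individuals", "n_thaws", "n_variants", "n_blocks", "n_antibodies"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_variants < self.n_blocks:
            raise ValueError("need n_variants >= n_blocks")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie within (0, 0.5]")
        if not (0 <= self.thaw_variance_fraction < 1):
            raise ValueError("thaw_variance_fraction must be in [0, 1)")
        if self.thaw_variance_fraction + self.residual_variance_fraction > 1:
            raise ValueError("thaw + residual variance fractions exceed 1")
        if self.noise_sd < 0 or self.drug_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        for r2 in self.apoptosis_cytotox_r2.values():
            if not (0 <= r2 <= 1):
                raise ValueError("target r^2 must be in [0, 1]")

    # deterministic independent substreams per generator stage
    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), stage])

    @property
    def individuals(self) -> list[str]:
        return [f"I{i:04d}" for i in range(self.n_individuals)]

    @property
    def antibodies(self) -> list[str]:
        return [f"AB{a:04d}" for a in range(self.n_antibodies)]

    @property
    def variant_ids(self) -> list[str]:
        return [f"var{v:06d}" for v in range(self.n_variants)]

    @property
    def phenotype_ids(self) -> list[str]:
        return [f"{d}_{e}" for d in sorted(self.apoptosis_cytotox_r2) for e in ENDPOINTS]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort, serializable losslessly."""

    pqtl_map: list[PlantedPQTL]
    drug_effect_map: list[PlantedDrugEffect]
    thaw_variance_fraction: dict  # antibody -> realized fraction
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "pqtl_map": [asdict(p) for p in self.pqtl_map],
            "drug_effect_map": [asdict(d) for d in self.drug_effect_map],
            "thaw_variance_fraction": self.thaw_variance_fraction,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            pqtl_map=[PlantedPQTL(**p) for p in payload["pqtl_map"]],
            drug_effect_map=[PlantedDrugEffect(**d) for d in payload["drug_effect_map"]],
            thaw_variance_fraction=payload["thaw_variance_fraction"],
            seed=payload["seed"],
        )


# ---------------------------------------------------------------------------
# genotypes


def _block_sizes(n_variants: int, n_blocks: int) -> np.ndarray:
    base = n_variants // n_blocks
    sizes = np.full(n_blocks, base)
    sizes[: n_variants - base * n_blocks] += 1
    return sizes


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, BlockPartition]:
    """Draw genotypes under HWE with block-structured LD.

    LD is emulated with a block copula: each recombination block carries a
    latent Gaussian factor per haplotype; a variant's allele indicator is a
    threshold of sqrt(rho)*factor + sqrt(1-rho)*noise at its MAF quantile,
    so dosages within a block are correlated while blocks are independent.
    """
    from scipy.stats import norm

    rng = cfg.rng(1)
    n, m = cfg.n_individuals, cfg.n_variants
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    sizes = _block_sizes(m, cfg.n_blocks)
    block_of = np.repeat(np.arange(cfg.n_blocks), sizes)

    rho = cfg.block_ld
    dosage = np.empty((m, n))
    start = 0
    for b, sz in enumerate(sizes):
        w = rng.standard_normal((1, n, 2))  # shared factor per haplotype
        e = rng.standard_normal((sz, n, 2))
        z = np.sqrt(rho) * w + np.sqrt(1 - rho) * e
        thr = norm.ppf(mafs[start : start + sz])[:, None, None]
        dosage[start : start + sz] = (z < thr).sum(axis=2)
        start += sz

    if cfg.dosage_mode:
        dosage = np.clip(dosage + rng.normal(0, cfg.dosage_noise_sd, dosage.shape), 0, 2)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage = dosage.astype(float)
        dosage[mask] = np.nan

    # genome layout: blocks tile chromosomes 1..22 round-robin; variants 5 kb apart
    chroms = (np.arange(cfg.n_blocks) % 22) + 1
    spacing = 5000
    pos = np.empty(m, dtype=int)
    block_rows = []
    chrom_cursor = {c: 1 for c in range(1, 23)}
    start = 0
    for b, sz in enumerate(sizes):
        c = chroms[b]
        p0 = chrom_cursor[c]
        pos[start : start + sz] = p0 + spacing * np.arange(sz)
        end = p0 + spacing * sz
        block_rows.append({"chrom": str(c), "start": p0 - 1, "end": end - 1})
        chrom_cursor[c] = end
        start += sz

    variants = pd.DataFrame(
        {
            "chrom": [str(c) for c in chroms[block_of]],
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "target_maf": mafs,
        },
        index=pd.Index(cfg.variant_ids, name="variant_id"),
    )
    dosages = pd.DataFrame(dosage, index=variants.index, columns=cfg.individuals)
    blocks = BlockPartition(
        pd.DataFrame(block_rows, index=pd.Index([f"blk{b:05d}" for b in range(cfg.n_blocks)], name="block_id"))
    )
    return GenotypeMatrix(variants, dosages), blocks


# ---------------------------------------------------------------------------
# proteins


def simulate_protein_matrix(
    cfg: SimulationConfig, geno: GenotypeMatrix
) -> tuple[ProteinMatrix, SyntheticTruth]:
    """Protein expression with planted pQTLs and a thaw variance component."""
    for p in cfg.planted_pqtls:
        if p.antibody_id not in cfg.antibodies:
            raise ValueError(f"planted antibody {p.antibody_id} not in panel")
        if p.variant_id not in geno.variants.index:
            raise ValueError(f"planted variant {p.variant_id} not in genotypes")

    rng = cfg.rng(2)
    n, k, a = cfg.n_individuals, cfg.n_thaws, cfg.n_antibodies
    f_t = cfg.thaw_variance_fraction
    f_r = cfg.residual_variance_fraction
    f_i = 1.0 - f_t - f_r
    sd_i, sd_t, sd_r = (cfg.noise_sd * np.sqrt(f) for f in (f_i, f_t, f_r))

    b = rng.normal(0, 1.0, size=(a, n)) * sd_i
    u = rng.normal(0, 1.0, size=(a, n, k)) * sd_t
    x = b[:, :, None] + u  # (antibody, individual, thaw)
    if cfg.n_cultures > 1:
        e = rng.normal(0, 1.0, size=(a, n, k, cfg.n_cultures)) * sd_r
    elif f_r > 0:
        x = x + rng.normal(0, 1.0, size=(a, n, k)) * sd_r

    ab_index = {ab: i for i, ab in enumerate(cfg.antibodies)}
    genetic = np.zeros((a, n))
    for p in cfg.planted_pqtls:
        dos = geno.dosages.loc[p.variant_id, cfg.individuals].to_numpy(dtype=float)
        if np.isnan(dos).any():
            obs = np.nanmean(dos)
            dos = np.where(np.isnan(dos), obs, dos)
        genetic[ab_index[p.antibody_id]] += p.beta * dos
    x = x + genetic[:, :, None]

    realized = {}
    for i, ab in enumerate(cfg.antibodies):
        vu = float(u[i].var())
        vb = float(b[i].var())
        tot = vb + vu + (sd_r**2 if f_r > 0 else 0.0)
        realized[ab] = vu / tot if tot > 0 else 0.0

    if cfg.n_cultures > 1:
        cols = pd.MultiIndex.from_product(
            [cfg.individuals, range(1, k + 1), range(1, cfg.n_cultures + 1)],
            names=["individual", "thaw", "culture"],
        )
        vals = (x[:, :, :, None] + e).reshape(a, -1)
        values = pd.DataFrame(vals, index=pd.Index(cfg.antibodies, name="antibody"), columns=cols)
    else:
        cols = pd.MultiIndex.from_product(
            [cfg.individuals, range(1, k + 1)], names=["individual", "thaw"]
        )
        values = pd.DataFrame(
            x.reshape(a, -1), index=pd.Index(cfg.antibodies, name="antibody"), columns=cols
        )

    prov = pd.DataFrame(index=values.index)
    truth = SyntheticTruth(
        pqtl_map=list(cfg.planted_pqtls),
        drug_effect_map=list(cfg.planted_drug_effects),
        thaw_variance_fraction=realized,
        seed=cfg.seed,
    )
    return ProteinMatrix(values=values, provenance=prov), truth


# ---------------------------------------------------------------------------
# drug phenotypes


def simulate_drug_phenotypes(cfg: SimulationConfig, prot: ProteinMatrix) -> pd.DataFrame:
    """Per-individual drug phenotypes with protein-mediated effects.

    Each phenotype is sum(beta * individual-mean protein) + noise.  Within a
    drug, the apoptosis and cytotoxicity residuals are drawn jointly so the
    realized squared correlation matches the configured target; the two
    endpoints are inversely related (growth inhibition vs caspase
    activation), so the planted correlation is negative.
    """
    for eff in cfg.planted_drug_effects:
        if eff.antibody_id not in prot.values.index:
            raise ValueError(f"planted drug effect references unknown antibody {eff.antibody_id}")
        if eff.phenotype_id not in cfg.phenotype_ids:
            raise ValueError(f"unknown phenotype {eff.phenotype_id}")

    rng = cfg.rng(3)
    means = prot.individual_means()  # antibody x individual
    means = means[cfg.individuals] if set(cfg.individuals) <= set(means.columns) else means
    individuals = list(means.columns)
    n = len(individuals)

    signal = {ph: np.zeros(n) for ph in cfg.phenotype_ids}
    for eff in cfg.planted_drug_effects:
        vals = means.loc[eff.antibody_id].to_numpy(dtype=float)
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros(n)
        signal[eff.phenotype_id] += eff.beta * z

    out = {}
    for drug, r2 in sorted(cfg.apoptosis_cytotox_r2.items()):
        g_a = signal[f"{drug}_apoptosis"]
        g_c = signal[f"{drug}_cytotoxicity"]
        s = cfg.drug_noise_sd
        target = -np.sqrt(r2)
        var_a, var_c = g_a.var() + s**2, g_c.var() + s**2
        cov_g = float(np.cov(g_a, g_c)[0, 1]) if n > 1 else 0.0
        rho = (target * np.sqrt(var_a * var_c) - cov_g) / (s**2) if s > 0 else 0.0
        if abs(rho) > 1:
            warnings.warn(
                f"{drug}: target r^2 {r2} unreachable given planted effects; correlation clipped"
            )
            rho = float(np.clip(rho, -1, 1))
        if s > 0:
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n) * s
        else:
            z = np.zeros((n, 2))
            # zero-noise limit: endpoints perfectly collinear at r^2 = 1
            if r2 == 1.0:
                g_c = -g_a
        out[f"{drug}_apoptosis"] = g_a + z[:, 0]
        out[f"{drug}_cytotoxicity"] = g_c + z[:, 1]

    growth = rng.standard_normal(n)
    for ab, beta in cfg.planted_growth_effects:
        vals = means.loc[ab].to_numpy(dtype=float)
        sd = vals.std()
        growth = growth + beta * ((vals - vals.mean()) / sd if sd > 0 else 0.0)
    out["growth"] = growth

    table = pd.DataFrame(out, index=pd.Index(individuals, name="individual"))
    if cfg.per_thaw_phenotypes:
        reps = []
        for t in range(1, cfg.n_thaws + 1):
            jitter = rng.normal(0, 0.1 * cfg.drug_noise_sd, size=table.shape)
            rep = table + jitter
            rep["thaw"] = t
            reps.append(rep.set_index("thaw", append=True))
        table = pd.concat(reps).sort_index()
    return table


# ---------------------------------------------------------------------------
# array features


def simulate_array_features(
    cfg: SimulationConfig,
    prot: ProteinMatrix,
    spot_noise_sd: float = 20.0,
    base_scale: float = 500.0,
    background_level: float = 100.0,
    qc_negative_fraction: float = 0.02,
    qc_low_snr_fraction: float = 0.03,
    load_sd: float = 0.3,
    array_shift_sd: float = 0.4,
) -> pd.DataFrame:
    """Spot-level features whose quantification recovers the protein matrix.

    One array per antibody; RPPA antibodies get 4 technical replicate spots,
    MWA antibodies 3, mirroring the two platforms' designs.  The spot signal
    is base_scale * 2^(x + load + array shift [+ batch]) + background +
    noise: per-sample load effects are shared across arrays (so the median
    across a print estimates them) and per-array shifts are removed by
    quantile normalization.  A configurable fraction of spots is forced to
    fail each feature-QC rule.
    """
    if spot_noise_sd < 0:
        raise ValueError("spot noise sd must be nonnegative")
    rng = cfg.rng(4)
    n_rppa = cfg.n_rppa_antibodies
    if n_rppa is None:
        n_rppa = int(round(cfg.n_antibodies * 198 / 441))
    antibodies = list(prot.values.index)
    platforms = {ab: ("RPPA" if i < n_rppa else "MWA") for i, ab in enumerate(antibodies)}
    samples = list(prot.values.columns)
    load = {s: rng.normal(0, load_sd) if load_sd > 0 else 0.0 for s in samples}
    abund = {ab: rng.normal(0, 1.0) for ab in antibodies}
    shift = {ab: rng.normal(0, array_shift_sd) if array_shift_sd > 0 else 0.0
             for ab in antibodies}
    mwa_batches = {}
    batch_offset = {}
    mwa_abs = [ab for ab in antibodies if platforms[ab] == "MWA"]
    for i, ab in enumerate(mwa_abs):
        bid = f"MWB{i // 24:03d}"  # ~24 antibodies per micro-western batch
        mwa_batches[ab] = bid
        if bid not in batch_offset:
            batch_offset[bid] = rng.normal(0, 0.3)

    rows = []
    for ab in antibodies:
        plat = platforms[ab]
        n_tech = 4 if plat == "RPPA" else 3
        batch = mwa_batches.get(ab, "RPPA")
        boff = batch_offset.get(batch, 0.0)
        x = prot.values.loc[ab]
        for s in samples:
            mu = base_scale * 2.0 ** (x[s] + abund[ab] + load[s] + shift[ab] + boff)
            for r in range(n_tech):
                sig = mu + background_level
                if spot_noise_sd > 0:
                    sig += rng.normal(0, spot_noise_sd)
                rows.append(
                    (
                        f"arr_{ab}",
                        batch,
                        plat,
                        s[0],
                        s[1],
                        r + 1,
                        ab,
                        max(sig, 0.0),
                        background_level,
                        max(spot_noise_sd, 1e-9),  # table requires positive noise_sd
                    )
                )
    feats = pd.DataFrame(
        rows,
        columns=[
            "array_id",
            "batch_id",
            "platform",
            "individual",
            "thaw",
            "tech_rep",
            "antibody",
            "signal",
            "background",
            "noise_sd",
        ],
    )
    # force QC failures: negative corrected intensity, then low S/N
    m = len(feats)
    fail_neg = rng.choice(m, size=int(qc_negative_fraction * m), replace=False)
    feats.loc[fail_neg, "signal"] = feats.loc[fail_neg, "background"] - np.abs(
        rng.normal(10, 5, size=fail_neg.size)
    )
    remaining = np.setdiff1d(np.arange(m), fail_neg)
    fail_snr = rng.choice(remaining, size=int(qc_low_snr_fraction * m), replace=False)
    feats.loc[fail_snr, "signal"] = (
        feats.loc[fail_snr, "background"] + 1.5 * feats.loc[fail_snr, "noise_sd"]
    )
    return feats


def simulate_gene_annotation(
    cfg: SimulationConfig, geno: GenotypeMatrix
) -> tuple[GeneAnnotation, pd.Series]:
    """A target gene per antibody, placed so planted cis/trans flags hold.

    cis-planted pQTLs put the gene within 100 kb of the variant; trans ones
    put it on another chromosome.  Unplanted antibodies get random loci.
    Returns the annotation and the antibody -> gene mapping.
    """
    rng = cfg.rng(5)
    gene_of = {}
    rows = {}
    planted = {p.antibody_id: p for p in cfg.planted_pqtls}
    for ab in cfg.antibodies:
        gid = f"GENE_{ab}"
        gene_of[ab] = gid
        p = planted.get(ab)
        if p is not None:
            var = geno.variants.loc[p.variant_id]
            if p.kind == "cis":
                chrom, tss = str(var["chrom"]), int(var["pos"]) + 100_000
            else:
                others = [c for c in map(str, range(1, 23)) if c != str(var["chrom"])]
                chrom = others[rng.integers(len(others))]
                tss = int(rng.integers(1_000_000, 100_000_000))
        else:
            chrom = str(rng.integers(1, 23))
            tss = int(rng.integers(1_000_000, 100_000_000))
        rows[gid] = {"chrom": chrom, "tss": tss, "tes": tss + 20_000, "strand": "+"}
    genes = GeneAnnotation(pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id"))
    return genes, pd.Series(gene_of, name="gene_id")


# ---------------------------------------------------------------------------
# planted coefficient blocks (cluster-recovery fixtures)


def simulate_coefficient_blocks(
    k: int,
    seed: int,
    n_rows: int = 370,
    n_cols: int = 4,
    separation: float = 5.0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-block matrix with k well-separated clusters for cluster-count tests.

    Cluster centers sit at the vertices of a regular simplex with Euclidean
    edge ``separation * sqrt(n_cols)`` (per-column RMS separation of
    ``separation`` noise SDs), randomly rotated so the separation is spread
    across columns — column shuffles cannot detect structure confined to a
    single column, so an unrotated layout would understate recoverability.
    Returns (matrix, true row labels).
    """
    if k < 1 or n_rows < k:
        raise ValueError("need 1 <= k <= n_rows")
    rng = np.random.default_rng([seed % (2**31), 9])
    V = np.eye(k) - 1.0 / k
    U, s, _ = np.linalg.svd(V, full_matrices=False)
    coords = (U[:, : k - 1] * s[: k - 1]) / np.sqrt(2) * separation * np.sqrt(n_cols)
    if coords.shape[1] < n_cols:
        coords = np.hstack([coords, np.zeros((k, n_cols - coords.shape[1]))])
    coords = coords[:, :n_cols]
    q, _ = np.linalg.qr(rng.standard_normal((n_cols, n_cols)))
    centers = coords @ q
    sizes = [n_rows // k + (1 if i < n_rows % k else 0) for i in range(k)]
    labels = np.repeat(np.arange(k), sizes)
    matrix = centers[labels] + rng.normal(0, noise_sd, size=(n_rows, n_cols))
    return matrix, labels


# ---------------------------------------------------------------------------
# siRNA


def simulate_sirna_experiment(
    effect: float,
    n_lines: int,
    n_experiments: int,
    seed: int,
    n_replicates: int = 8,
    baseline: float = 1000.0,
    line_sd: float = 0.2,
    experiment_sd: float = 0.1,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Knockdown-vs-scrambled response table with random line/experiment intercepts.

    ``effect`` is a multiplicative change (-0.119 means an 11.9% reduction in
    the response under knockdown).  Responses are lognormal around the
    baseline.  Returns rows (line, experiment, knockdown, response).
    """
    if n_lines < 1 or n_experiments < 1:
        raise ValueError("need at least one line and one experiment")
    rng = np.random.default_rng([seed % (2**31), 6])
    log_eff = np.log1p(effect)
    line_e = rng.normal(0, line_sd, size=n_lines)
    exp_e = rng.normal(0, experiment_sd, size=n_experiments)
    rows = []
    for li in range(n_lines):
        for xi in range(n_experiments):
            for kd in (0, 1):
                for _ in range(n_replicates):
                    resp = baseline * np.exp(
                        line_e[li] + exp_e[xi] + kd * log_eff + rng.normal(0, noise_sd)
                    )
                    rows.append((f"line{li}", f"exp{xi}", kd, resp))
    return pd.DataFrame(rows, columns=["line", "experiment", "knockdown", "response"])
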