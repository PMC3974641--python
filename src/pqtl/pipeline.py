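"""End-to-end pipeline driver: simulate -> quantify -> assoc -> qtl -> enrich
-> triangulate -> cluster, with per-stage toggles, seeded determinism and
audit logging of record counts."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .array_quant import quantify_features
from .assoc import assoc_scan
from .cluster import build_coefficient_matrix, dendrogram_newick, permutation_k
from .enrichment import run_enrichment
from .qtl import (
    gwas_scan,
    best_per_block,
    inverse_normal_transform,
    mean_impute,
    qc_filter,
)
from .simulate import (
    PlantedDrugEffect,
    PlantedPQTL,
    SimulationConfig,
    simulate_array_features,
    simulate_drug_phenotypes,
    simulate_genotypes,
    simulate_protein_matrix,
)
from .triangulate import cross_phenotype_overlap, triangulate

log = logging.getLogger("pqtl.pipeline")

STAGES = ("simulate", "quantify", "assoc", "qtl", "enrich", "triangulate", "cluster")


@dataclass
class PipelineConfig:
    """Every printed threshold of the analysis, in one validated place."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    dqtl_p: float = 1e-3
    pqtl_p: float = 1e-4
    prot_p: float = 0.05
    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    snr_min: float = 3.0
    n_perm: int = 1000
    maf_bin_width: float = 0.02
    cis_window: int = 1_000_000
    cluster_n_perm: int = 1000
    simulation: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        checks = [
            (0 < self.dqtl_p < 1, "dqtl_p"),
            (0 < self.pqtl_p < 1, "pqtl_p"),
            (0 < self.prot_p <= 1, "prot_p"),
            (0 <= self.maf_min <= 0.5, "maf_min"),
            (0 <= self.hwe_p_min < 1, "hwe_p_min"),
            (self.snr_min >= 0, "snr_min"),
            (self.n_perm >= 1, "n_perm"),
            (0 < self.maf_bin_width <= 0.5, "maf_bin_width"),
            (self.cis_window > 0, "cis_window"),
            (self.cluster_n_perm >= 1, "cluster_n_perm"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"{name} outside its valid range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        if "planted_pqtls" in sim:
            sim["planted_pqtls"] = tuple(
                PlantedPQTL(**p) if isinstance(p, dict) else p for p in sim["planted_pqtls"]
            )
        if "planted_drug_effects" in sim:
            sim["planted_drug_effects"] = tuple(
                PlantedDrugEffect(**p) if isinstance(p, dict) else p
                for p in sim["planted_drug_effects"]
            )
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        return SimulationConfig(**sim)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the toggled stages end-to-end, writing artifacts under out_dir.

    Returns a manifest dict (also written as manifest.json) with the config
    hash, per-stage record counts and timings.  Stage failures halt the run
    with the stage name; artifacts written so far are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}
    state: dict = {}

    def record(stage, t0, **counts):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **counts}
        log.info("stage %s: %s", stage, counts)

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            if stage == "simulate":
                sim = config.simulation_config()
                geno, blocks = simulate_genotypes(sim)
                prot, truth = simulate_protein_matrix(sim, geno)
                phen = simulate_drug_phenotypes(sim, prot)
                feats = simulate_array_features(sim, prot)
                pio.write_genotype_tsv(geno, out / "genotypes.tsv")
                pio.write_vcf(geno, out / "genotypes.vcf")
                pio.write_blocks_bed(blocks, out / "blocks.bed")
                pio.write_protein_tsv(prot, out / "proteins_true.tsv")
                pio.write_phenotype_tsv(phen, out / "phenotypes.tsv")
                pio.write_feature_tsv(feats, out / "features.tsv")
                truth.to_json(out / "truth.json")
                state.update(sim=sim, geno=geno, blocks=blocks, prot_true=prot, phen=phen,
                             feats=feats, truth=truth)
                record(stage, t0, variants=geno.n_variants, individuals=len(geno.individuals),
                       antibodies=len(prot.antibodies), features=len(feats))
            elif stage == "quantify":
                prot = quantify_features(state["feats"], snr_min=config.snr_min)
                pio.write_protein_tsv(prot, out / "proteins.tsv", out / "provenance.tsv")
                state["prot"] = prot
                record(stage, t0, antibodies_in=state["feats"]["antibody"].nunique(),
                       antibodies_out=len(prot.antibodies))
            elif stage == "assoc":
                prot = state.get("prot", state.get("prot_true"))
                assoc = assoc_scan(prot, state["phen"], model="MEM")
                assoc.to_csv(out / "assoc.tsv", sep="\t", index=False)
                state["assoc"] = assoc
                record(stage, t0, fits=len(assoc),
                       nominal=int((assoc["p"] < 0.05).sum()))
            elif stage == "qtl":
                geno = qc_filter(state["geno"], maf_min=config.maf_min,
                                 hwe_p_min=config.hwe_p_min)
                geno.dosages = pd.DataFrame(
                    mean_impute(geno.dosages.to_numpy(dtype=float)),
                    index=geno.dosages.index, columns=geno.dosages.columns,
                )
                state["geno_qc"] = geno
                prot = state.get("prot", state.get("prot_true"))
                prot_traits = prot.individual_means().T
                prot_traits = prot_traits.apply(
                    lambda c: inverse_normal_transform(c.to_numpy()), axis=0,
                    result_type="broadcast",
                )
                pqtl = gwas_scan(geno, prot_traits, trait_class="protein")
                drug_cols = [c for c in state["phen"].columns if c != "growth"]
                dqtl = gwas_scan(geno, state["phen"][drug_cols], trait_class="drug")
                pio.write_qtl_tsv(pqtl, out / "pqtl.tsv")
                pio.write_qtl_tsv(dqtl, out / "dqtl.tsv")
                state["pqtl"], state["dqtl"] = pqtl, dqtl
                record(stage, t0, variants_post_qc=geno.n_variants,
                       pqtl_rows=len(pqtl), dqtl_rows=len(dqtl))
            elif stage == "enrich":
                results = {}
                for ph in state["dqtl"]["trait_id"].unique():
                    res = run_enrichment(
                        state["dqtl"][state["dqtl"]["trait_id"] == ph],
                        state["pqtl"], state["geno_qc"], state["blocks"],
                        phenotype_id=ph, dqtl_threshold=config.dqtl_p,
                        qtl_threshold=config.pqtl_p, n_perm=config.n_perm,
                        maf_bin_width=config.maf_bin_width, seed=config.seed,
                    )
                    res.to_json(out / f"enrichment_{ph}.json")
                    res.to_tsv(out / f"enrichment_{ph}.tsv")
                    results[ph] = res
                state["enrichment"] = results
                record(stage, t0, phenotypes=len(results),
                       min_empirical_p=min(r.empirical_p for r in results.values()))
            elif stage == "triangulate":
                tri = {}
                drugs = sorted({ph.rsplit("_", 1)[0] for ph in state["dqtl"]["trait_id"].unique()})
                for drug in drugs:
                    for endpoint in ("apoptosis", "cytotoxicity"):
                        ph = f"{drug}_{endpoint}"
                        sub = state["dqtl"][state["dqtl"]["trait_id"] == ph]
                        res = triangulate(
                            sub, state["pqtl"], state["assoc"], drug, endpoint,
                            dqtl_p=config.dqtl_p, pqtl_p=config.pqtl_p,
                            prot_p=config.prot_p,
                        )
                        res.triplets.to_csv(out / f"triplets_{ph}.tsv", sep="\t", index=False)
                        tri[ph] = res
                summary = {
                    ph: {"snps": r.implicated_snps, "proteins": r.implicated_proteins}
                    for ph, r in tri.items()
                }
                for drug in drugs:
                    overlap = cross_phenotype_overlap(
                        tri[f"{drug}_apoptosis"], tri[f"{drug}_cytotoxicity"]
                    )
                    summary[f"{drug}_overlap"] = sorted(overlap)
                (out / "triangulation.json").write_text(json.dumps(summary, indent=1))
                state["triangulation"] = tri
                record(stage, t0, triplets=sum(len(r.triplets) for r in tri.values()))
            elif stage == "cluster":
                cm = build_coefficient_matrix(state["assoc"])
                sol = permutation_k(cm, n_perm=config.cluster_n_perm, seed=config.seed)
                sol.assignments.to_csv(out / "clusters.tsv", sep="\t")
                (out / "dendrogram.nwk").write_text(
                    dendrogram_newick(sol.linkage, list(cm.values.index))
                )
                (out / "cluster_summary.json").write_text(json.dumps(
                    {"k": sol.k, "p": sol.p, "cut_height": None if np.isnan(sol.cut_height)
                     else sol.cut_height}))
                state["clusters"] = sol
                record(stage, t0, rows=len(cm.values), k=sol.k, p=sol.p)
        except Exception as exc:  # halt with stage name; partial outputs retained
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    state["manifest"] = manifest
    return state
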