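import warnings

import numpy as np
import pytest

from pqtl.simulate import (
    PlantedDrugEffect,
    PlantedPQTL,
    SimulationConfig,
    simulate_array_features,
    simulate_drug_phenotypes,
    simulate_genotypes,
    simulate_protein_matrix,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale cohort with planted pQTL, drug and growth effects."""
    return SimulationConfig(
        n_individuals=50,
        n_variants=300,
        n_blocks=30,
        n_antibodies=40,
        seed=11,
        planted_pqtls=(
            PlantedPQTL("var000010", "AB0003", 1.0, "cis"),
            PlantedPQTL("var000200", "AB0007", 0.8, "trans"),
        ),
        planted_drug_effects=(
            PlantedDrugEffect("AB0003", "paclitaxel_apoptosis", 0.6),
            PlantedDrugEffect("AB0003", "paclitaxel_cytotoxicity", -0.5),
        ),
        planted_growth_effects=(("AB0005", 0.7),),
    )


@pytest.fixture(scope="session")
def cohort(small_cfg):
    geno, blocks = simulate_genotypes(small_cfg)
    prot, truth = simulate_protein_matrix(small_cfg, geno)
    phen = simulate_drug_phenotypes(small_cfg, prot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = simulate_array_features(small_cfg, prot)
    return {
        "cfg": small_cfg,
        "geno": geno,
        "blocks": blocks,
        "prot": prot,
        "truth": truth,
        "phen": phen,
        "feats": feats,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
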