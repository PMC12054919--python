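import numpy as np
import pandas as pd
import pytest

from lactovar import grm, syndata


@pytest.fixture(scope="session")
def small_cohort():
    """500 animals x 1000 variants with a planted 30% functional class."""
    cfg = syndata.SimConfig(
        n_individuals=500,
        n_variants=1000,
        n_chromosomes=2,
        seed=42,
        class_specs=[
            syndata.ClassSpec("qtl", 0.3, (0.8, 0.1, 0.07, 0.03)),
            syndata.ClassSpec("other", 0.0, (0.95, 0.03, 0.015, 0.005)),
        ],
        h2_target=0.6,
    )
    geno = syndata.sim_genotypes(cfg)
    cmap = syndata.sim_class_map(geno, cfg)
    truth, pheno = syndata.sim_effects_and_phenotypes(geno, cmap, cfg)
    return cfg, geno, cmap, truth, pheno


@pytest.fixture
def tiny_geno():
    """Hand-sized panel for arithmetic checks."""
    dosages = np.array(
        [[0.0, 1.0, 2.0, 1.0], [2.0, 1.0, 0.0, 1.0], [1.0, 1.0, 1.0, 1.0]]
    )
    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [10, 50, 120, 300],
            "id": [f"v{i}" for i in range(4)],
            "ref": ["A"] * 4,
            "alt": ["G"] * 4,
        }
    )
    return grm.GenotypeMatrix(dosages, variants, np.array(["s1", "s2", "s3"]))
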