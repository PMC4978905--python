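import numpy as np
import pandas as pd
import pytest

import nilqtl as nq


@pytest.fixture(scope="session")
def small_dataset():
    """3 populations x 60 lines, one 100 cM chromosome, one strong planted QTL."""
    cfg = nq.SimConfig(
        n_populations=3, lines_per_population=60,
        chromosomes=[(100.0, 21)],
        environments=2, reps_per_environment=2,
        traits=("y",), trait_means={"y": 10.0},
        qtl=[nq.PlantedQTL(1, 50.0, {"y": 1.2})],
        residual_sd=0.4, env_effect_sd=0.3, gxe_sd=0.15, rep_sd=0.1,
        pop_mean_sd=0.3, monomorphic_fraction=0.0, seed=11,
    )
    geno, gmap, pheno = nq.simulate_dataset(cfg)
    return cfg, geno, gmap, pheno


@pytest.fixture(scope="session")
def small_means(small_dataset):
    _, _, _, pheno = small_dataset
    return nq.compute_line_means(pheno)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def kernel_means():
    """Correlated multi-trait line means resembling kernel measurements."""
    rng = np.random.default_rng(7)
    n = 400
    size = rng.normal(size=n)             # latent kernel size
    shape = rng.normal(size=n)            # latent shape axis
    means = pd.DataFrame({
        "line_id": [f"L{i:04d}" for i in range(n)],
        "population": np.repeat([f"Z{k:03d}" for k in range(1, 5)], n // 4),
        "area": 58 + 4 * size + 0.8 * rng.normal(size=n),
        "length": 11 + 0.5 * size + 0.2 * shape + 0.1 * rng.normal(size=n),
        "width": 6.5 + 0.25 * size - 0.15 * shape + 0.08 * rng.normal(size=n),
        "Wt50k": 12.6 + 1.0 * size + 0.4 * rng.normal(size=n),
        "roundness": 81 - 1.5 * shape + 0.7 * rng.normal(size=n),
        "perimeter": 32 + 1.2 * size + 0.3 * shape + 0.3 * rng.normal(size=n),
    })
    return means
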