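import numpy as np
import pandas as pd
import pytest

from metaboqtl.simulate import SimulationConfig, simulate_covariates, simulate_genotypes


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_animals=60, n_snps=120, n_chromosomes=5, n_metabolites=4, seed=42
    )


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_covariates(small_config):
    return simulate_covariates(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def toy_annotation():
    """Hand-laid genes on two chromosomes for window-mapping edge cases."""
    return pd.DataFrame(
        {
            "gene_id": ["g_in", "g_edge", "g_out", "g_mirna", "g_chr2"],
            "symbol": ["IN", "EDGE", "OUT", "MIR1", "CHR2"],
            "chrom": ["1", "1", "1", "1", "2"],
            "start": [1_065_000, 1_070_000, 1_070_001, 1_000_100, 1_000_000],
            "end": [1_090_000, 1_090_000, 1_090_000, 1_000_200, 1_010_000],
            "biotype": ["protein_coding"] * 3 + ["miRNA", "protein_coding"],
        }
    )
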