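import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from xtwas.simulate import SimulationConfig, simulate_expression, simulate_genotypes


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    """A small multi-tissue study used by several structural tests."""
    return SimulationConfig(
        seed=11, n_ref=300, n_gwas=20_000, n_snps_per_gene=8, n_genes=6,
        n_tissues=3, ld_rho=0.5, h2_expr=0.4, n_causal_eqtl=2,
        causal_gene_frac=0.5, gene_effect_sd=0.2,
        tissue_sample_fracs=(0.9, 0.7, 0.5),
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_cfg):
    panel = simulate_genotypes(tiny_cfg)
    tissue_sets, truth = simulate_expression(panel, tiny_cfg)
    return panel, tissue_sets, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
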