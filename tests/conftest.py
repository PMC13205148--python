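import numpy as np
import pandas as pd
import pytest

from maizecore import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """60 lines x 300 SNPs, 2 envs x 3 blocks — shared across test modules."""
    cfg = SimConfig(n_lines=60, n_snps=300, seed=11)
    geno, pheno, truth = simulate_panel(cfg)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def small_blups(small_panel):
    from maizecore import extract_blups, fit_all_traits

    _, _, pheno, _ = small_panel
    return extract_blups(fit_all_traits(pheno))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
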