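import numpy as np
import pytest

from allelreg.config import LDBlockSpec, SimulationConfig
from allelreg import synthdata


@pytest.fixture(scope="session")
def config():
    """Default study-scale configuration, fixed seed."""
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def small_config():
    """A cheap configuration for structural tests."""
    return SimulationConfig(
        n_samples=60,
        ld_block_spec=(LDBlockSpec(6, 2, (0.5, 0.5)),
                       LDBlockSpec(6, 3, (0.4, 0.4, 0.2))),
        risk_variant_index=2,
        n_genes=200,
        planted_sets=(),
        n_reads=200,
        seed=11,
    )


@pytest.fixture(scope="session")
def panel(config):
    return synthdata.simulate_haplotype_panel(config)


@pytest.fixture(scope="session")
def genotypes(config, panel):
    return synthdata.panel_to_genotypes(panel)


@pytest.fixture(scope="session")
def exon_expression(config, genotypes):
    return synthdata.simulate_exon_expression(genotypes, config)


def pairwise_r2_bruteforce(haplotypes: np.ndarray, i: int, j: int) -> float:
    """Independent r2 oracle: squared Pearson correlation of the two
    haplotype indicator columns."""
    a = haplotypes[:, i].astype(float)
    b = haplotypes[:, j].astype(float)
    return float(np.corrcoef(a, b)[0, 1] ** 2)
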