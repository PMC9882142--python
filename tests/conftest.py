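import numpy as np
import pytest

from dualvar.simulate import (SimConfig, simulate_diploid, simulate_methylation,
                              simulate_reads)


@pytest.fixture(scope="session")
def small_truth():
    """A small diploid dataset with reads, shared across tests."""
    cfg = SimConfig(seed=42, genome_len=120_000, n_svs=24, n_vntrs=6,
                    coverage=30, read_error=0.01, meth_regions=30)
    truth = simulate_diploid(cfg)
    simulate_reads(truth, cfg)
    return cfg, truth


@pytest.fixture(scope="session")
def clean_truth():
    """Error-free reads at moderate coverage (for exactness checks)."""
    cfg = SimConfig(seed=7, genome_len=120_000, n_svs=24, n_vntrs=6,
                    coverage=16, read_error=0.0, meth_regions=30)
    truth = simulate_diploid(cfg)
    simulate_reads(truth, cfg)
    return cfg, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
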