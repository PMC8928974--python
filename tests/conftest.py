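import numpy as np
import pytest

from dirscreen import simdata
from dirscreen.snp_library import SnpRecord, build_library


@pytest.fixture(scope="session")
def small_panel():
    rng = np.random.default_rng(42)
    return simdata.synthetic_panel(20, rng)


@pytest.fixture(scope="session")
def small_library(small_panel):
    return build_library(small_panel, seed=42)


@pytest.fixture(scope="session")
def small_study():
    """20-SNP study at modest depth, deterministic."""
    cfg = simdata.SimConfig(n_snps=20, read_depth=100_000, seed=7)
    return simdata.simulate_study(cfg)
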