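import logging

import numpy as np
import pytest

from flexcfdr import SimScenario, build_ld_layout, prune_independent_subset, simulate_gwas

logging.getLogger("flexcfdr").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def desk_layout():
    """Default study layout: 24 AR(1) blocks, ~10k SNPs, chr22-like density."""
    return build_ld_layout()


@pytest.fixture(scope="session")
def desk_indep(desk_layout):
    return prune_independent_subset(desk_layout, 0.1)


@pytest.fixture(scope="session")
def signal_study(desk_layout):
    """One simulated GWAS with causal signals, reused across read-only tests."""
    return simulate_gwas(desk_layout, SimScenario(scenario="C"), seed=1234)


def write_tsv(path, df):
    df.to_csv(path, sep="\t", index=False)
    return path
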