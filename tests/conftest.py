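import numpy as np
import pytest

from fitscreen import simkit


@pytest.fixture(scope="session")
def marker_sets():
    """Five disjoint marker sets, five genes per phase."""
    return {p: [f"{p}_M{i}" for i in range(5)] for p in simkit.PHASES}


@pytest.fixture(scope="session")
def four_group_cfg():
    """Small cohort covering all four genotype groups (2/2/3/3)."""
    return simkit.SimConfig(
        n_genes=10,
        n_lines=10,
        group_sizes={"HomDel": 2, "T_HetDel": 2, "HetDel": 3, "WT": 3},
    )


def make_null_sl_config(seed, n_genes=2000, n_mut=5, n_wt=200):
    return simkit.SimConfig(
        n_genes=n_genes,
        n_lines=n_mut + n_wt,
        group_sizes={"HomDel": n_mut, "WT": n_wt},
        seed=seed,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230517)
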