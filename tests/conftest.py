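import pytest

from omicid import SimConfig, simulate_array, simulate_counts, simulate_truth


@pytest.fixture(scope="session")
def default_truth():
    """Default 10-individual cohort, seed 1."""
    return simulate_truth(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_beta(default_truth):
    return simulate_array(default_truth)


@pytest.fixture(scope="session")
def default_wgs_counts(default_truth):
    return simulate_counts(default_truth, "wgs")


@pytest.fixture(scope="session")
def tiny_truth():
    """Small cohort for fast I/O round trips."""
    return simulate_truth(
        SimConfig(seed=7, n_individuals=3, n_array_loci=6, n_exonic_loci=12, n_genes=30)
    )
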