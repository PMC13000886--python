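import numpy as np
import pytest

from basketbhm import (
    McmcConfig,
    ScenarioConfig,
    center_covariates,
    generate_scenario,
    run_cell,
)

# One base seed for the whole suite; per-cell data seeds are derived from it
# by the runner's hashing scheme.
BASE_SEED = 0


@pytest.fixture(scope="session")
def mcmc_default():
    return McmcConfig()


@pytest.fixture(scope="session")
def s2_dataset():
    """One centered scenario-2 dataset at the largest study size."""
    cfg = ScenarioConfig("S2", 560, allocation_fraction=0.5, seed=BASE_SEED)
    return center_covariates(generate_scenario(cfg))


@pytest.fixture(scope="session")
def cell_s1_a075():
    """Scenario (1), allocation 0.75, n=560: the headline study cell.

    200 paired replicates of the unadjusted and interaction-adjusted
    hierarchical models.
    """
    return run_cell(
        "S1", 560, 0.75, ["BHM", "intBHM"], B=200, base_seed=BASE_SEED,
        mcmc=McmcConfig(), reference_method="BHM",
    )


@pytest.fixture(scope="session")
def cell_s1_a05():
    """Scenario (1), equal allocation, n=560, 100 paired replicates."""
    return run_cell(
        "S1", 560, 0.5, ["BHM", "intBHM"], B=100, base_seed=BASE_SEED,
        mcmc=McmcConfig(), reference_method="BHM",
    )


@pytest.fixture(scope="session")
def cell_s2_a05():
    """Scenario (2), equal allocation, n=560, 100 paired replicates of all
    three hierarchical models."""
    return run_cell(
        "S2", 560, 0.5, ["BHM", "adjBHM", "intBHM"], B=100, base_seed=BASE_SEED,
        mcmc=McmcConfig(), reference_method="BHM",
    )


@pytest.fixture(scope="session")
def cell_s1_freq():
    """Scenario (1), allocation 0.75, n=560: stratified fits at full B=1000."""
    return run_cell(
        "S1", 560, 0.75, ["sANOVA", "sANCOVAII"], B=1000, base_seed=BASE_SEED,
        mcmc=McmcConfig(), reference_method="sANOVA",
    )
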