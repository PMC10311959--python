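import numpy as np
import pytest

from speedirt import (
    CovariateTable,
    MCMCConfig,
    ResponseMatrix,
    SimulationScenario,
    code_missingness,
    generate_dataset,
)

M = np.nan


@pytest.fixture
def toy_response() -> ResponseMatrix:
    """Six persons, six items, covering full rows, skips and terminal runs."""
    values = np.array([
        [1, 0, 1, 0, 1, 1],
        [M, M, M, M, M, M],
        [1, 0, M, 1, M, M],
        [1, 1, 1, 1, 1, M],
        [1, M, M, M, M, M],
        [0, 1, 0, M, M, M],
    ])
    return ResponseMatrix(values)


@pytest.fixture
def toy_covariates() -> CovariateTable:
    return CovariateTable(
        gender=[1, 1, 0, 0, 1, 1],
        condition=[0, 1, 0, 1, 0, 1],
        subsample=["a", "a", "a", "b", "b", "b"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort shared by sampler-level smoke tests."""
    scen = SimulationScenario(N=60, K=5, seed=11)
    data = generate_dataset(scen)
    return data, code_missingness(data.responses)


@pytest.fixture
def fast_cfg() -> MCMCConfig:
    return MCMCConfig(n_chains=2, n_adapt=60, n_burnin=60, n_posterior_total=200,
                      seed=7, escalated_burnin=120)
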