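import numpy as np
import pytest

from symptomdx import (
    EpidemiologicalMeasures,
    default_grid,
    run_grid,
    simulate_cohort,
)

FIG3_SEED = 20220815  # fixed root seed for the worked-example cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fig3_measures():
    """The worked-example configuration: d=0.05, ir=0.1, rr=2, no correlations."""
    return EpidemiologicalMeasures(d=0.05, ir=0.1, rr=2.0, rho_dd=0.0,
                                   rho_ss=0.0, n_subjects=10_000,
                                   n_symptoms=40, seed=FIG3_SEED)


@pytest.fixture(scope="session")
def fig3_cohort(fig3_measures):
    return simulate_cohort(fig3_measures)


@pytest.fixture(scope="session")
def small_grid_results():
    """A small but two-stratum grid for structural tests (fast)."""
    # ir and rr must both vary inside the capped stratum so that the
    # stratified meta-models keep their full covariate sets
    grid = default_grid(
        n_subjects=600, n_symptoms=8,
        rho_dd=(0.0, 0.3), d=(0.1, 0.4), ir=(0.1, 0.4, 0.8),
        rr=(0.5, 2.0, 5.0), rho_ss=(0.0, 0.4))
    return run_grid(grid, replicates=2, base_seed=99)
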