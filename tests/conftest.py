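import numpy as np
import pandas as pd
import pytest

from coxcal import SurvivalDataset, fit_cox, simulate_cohort
from coxcal.experiments import run_type1_study
from coxcal.simulate import SimulationConfig


@pytest.fixture()
def toy_two_subjects() -> SurvivalDataset:
    """Two subjects, events at t=1 and t=2, one covariate with no variation."""
    return SurvivalDataset(
        time=np.array([1.0, 2.0]),
        event=np.array([1, 1]),
        covariates=pd.DataFrame({"z1": [0.0, 0.0]}),
    )


@pytest.fixture(scope="session")
def small_null_cohort() -> SurvivalDataset:
    """n=500 cohort simulated and fitted under the same 5-SNP model."""
    cfg = SimulationConfig(n=500, model="g01", p=5, target_event_rate=0.2, seed=101)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_null_fit(small_null_cohort):
    return fit_cox(small_null_cohort)


@pytest.fixture(scope="session")
def null_study_large():
    """2000 replicates of the reference null scenario.

    n=5000 subjects, 5 SNPs (Binomial(2, 0.3)), per-SNP log-HR log(1.2),
    constant baseline hazard, scale calibrated to a 5% ten-year event
    rate, administrative censoring only; the correctly specified Cox model
    is fitted and both calibration tests are run at D=11 with 1000 inner
    null replicates. Shared across the type-I-error and null-distribution
    tests (the dominant cost of the suite).
    """
    cfg = SimulationConfig(n=5000, model="g01", p=5, target_event_rate=0.05)
    return run_type1_study(cfg, n_replicates=2000, seed=20180522)
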