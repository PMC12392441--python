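import numpy as np
import pytest
from hypothesis import settings

from pegscission import EnsembleSpec
from pegscission.fitting import FitConfig, simulate_grid_curves
from pegscission.simulate import sic_trajectory

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_spec() -> EnsembleSpec:
    """The study conditions: 5000 chains, 6380 +/- 400 Da, 44-Da repeat."""
    return EnsembleSpec.from_mw(m=5000, mn0_da=6380.0, sigma_da=400.0)


@pytest.fixture(scope="session")
def fit_config(study_spec) -> FitConfig:
    """Default grid-fit configuration (grid 0:8:0.1, 50 replicates)."""
    return FitConfig(spec=study_spec, replicates=50, base_seed=20260920)


@pytest.fixture(scope="session")
def grid_curves_default(fit_config):
    """One checkpointed replicate set shared by every grid-fit test."""
    return simulate_grid_curves(fit_config)


@pytest.fixture(scope="session")
def trajectory_df(study_spec):
    """wt% traces of the 6380/4400/440-Da classes over SiC 0..8."""
    grid = np.round(np.arange(0.0, 8.25, 0.25), 10)
    return sic_trajectory(
        study_spec,
        sic_grid=grid,
        target_mws=[6380.0, 4400.0, 440.0],
        n_replicates=50,
        base_seed=42,
    )
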