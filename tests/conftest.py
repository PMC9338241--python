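import numpy as np
import pytest

from gaitclass.pipeline import RunConfig
from gaitclass.synthetic_cohort import CohortConfig, LatentRunner, simulate_trial


@pytest.fixture
def noise_free_config() -> CohortConfig:
    """Single-speed generator config with all noise sources off."""
    return CohortConfig(
        n_runners=3, speeds=(9.0,), noise_sd_force=0.0, noise_sd_angle=0.0, seed=123
    )


@pytest.fixture
def reference_runner() -> LatentRunner:
    """A rearfoot striker with round-number gait parameters."""
    return LatentRunner(
        runner_id=1, speed=9.0, true_df=0.35, true_fsa=13.3, true_sf=1.4,
        body_mass=70.0, static_offset=5.0,
    )


@pytest.fixture
def noise_free_trial(reference_runner, noise_free_config):
    return simulate_trial(reference_runner, noise_free_config)


@pytest.fixture
def run_config() -> RunConfig:
    return RunConfig()
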