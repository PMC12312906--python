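import numpy as np
import pytest

from locolearn.core_model import HeightClass, ObstacleSpec, OutputVariant
from locolearn.inference import HierarchicalModelSpec, MCMCSettings, fit
from locolearn.synthetic_cohort import (
    CohortDesign,
    default_populations,
    generate_cohort,
)

LOW = ObstacleSpec(HeightClass.LOW, 0.05, 0.05, 0.09)
HIGH = ObstacleSpec(HeightClass.HIGH, 0.18, 0.01, 0.05)


@pytest.fixture(scope="session")
def low_spec():
    return LOW


@pytest.fixture(scope="session")
def high_spec():
    return HIGH


@pytest.fixture(scope="session")
def small_design():
    """Reduced study layout used for fast inference tests."""
    return CohortDesign(
        n_control=6,
        n_pd=5,
        n_acquisition=96,
        bout_size=32,
        no_feedback_bout=2,
        n_baseline_per_height=16,
        n_retention_per_height=8,
        baseline_fc_mean={HeightClass.LOW: 0.18, HeightClass.HIGH: 0.13},
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    pops = default_populations()
    return generate_cohort(pops[0], pops[1], small_design, seed=11)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """One reduced-scale FULL-model fit shared across inference tests."""
    spec = HierarchicalModelSpec(output_variant=OutputVariant.SELECT)
    mcmc = MCMCSettings(n_chains=3, n_iter=2000, burn_in=1000, thin=2, seed=7)
    return fit(small_cohort.trials, spec, mcmc), spec, mcmc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
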