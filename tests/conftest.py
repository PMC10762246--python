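import pytest

from socialdrift.design import DesignConfig
from socialdrift.preprocessing import apply_trial_filters
from socialdrift.synthetic import LatencyModel, PopulationSpec, simulate_experiment


@pytest.fixture(scope="session")
def exp1_config():
    return DesignConfig(experiment=1, seed=3)


@pytest.fixture(scope="session")
def clean_population():
    """Experiment-1-like population with a latency tail short enough that a
    well-behaved subject essentially never exceeds the late-response rule."""
    return PopulationSpec.experiment1(
        n_subjects=12, latency=LatencyModel.calibrated(1.0, 2.0, 0.25)
    )


@pytest.fixture(scope="session")
def exp1_simulation(exp1_config):
    """Shared 20-subject synthetic experiment at the default population."""
    return simulate_experiment(
        PopulationSpec.experiment1(n_subjects=20), exp1_config, seed=31
    )


@pytest.fixture(scope="session")
def ordinal_dataset(exp1_simulation):
    return apply_trial_filters(exp1_simulation.dataset, "ordinal")
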