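import pytest

from dielspec import FitConfig, FrequencyGrid, lung_parameter_table


@pytest.fixture(scope="session")
def lung_table():
    return lung_parameter_table()


@pytest.fixture(scope="session")
def default_grid():
    return FrequencyGrid.default()


@pytest.fixture()
def light_config():
    """Cheaper annealing budget for tests that only need basin-finding."""
    return FitConfig(seed=7, n_restarts=2, max_evaluations=20_000)
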