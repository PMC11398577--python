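import numpy as np
import pytest
from hypothesis import settings

from alstim.sweep_data import ParameterSweepTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def linear_table() -> ParameterSweepTable:
    """Noiseless table whose response is exactly linear in the parameters."""
    rng = np.random.default_rng(42)
    params = np.column_stack(
        [rng.uniform(50, 500, 60), rng.uniform(5, 185, 60), rng.uniform(50, 500, 60)]
    )
    y = 0.5 + 0.002 * params[:, 0] - 0.001 * params[:, 1] + 0.0005 * params[:, 2]
    return ParameterSweepTable(parameters=params, responses=y)


@pytest.fixture
def noisy_linear_table() -> ParameterSweepTable:
    rng = np.random.default_rng(7)
    params = np.column_stack(
        [rng.uniform(50, 500, 80), rng.uniform(5, 185, 80), rng.uniform(50, 500, 80)]
    )
    y = 0.5 + 0.002 * params[:, 0] - 0.001 * params[:, 1] + 0.0005 * params[:, 2]
    y = y + rng.normal(0, 0.05, 80)
    return ParameterSweepTable(parameters=params, responses=y)
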