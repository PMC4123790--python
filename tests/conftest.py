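import numpy as np
import pytest

from oridir import (
    AngleGrid,
    NoiseModel,
    TrialResponses,
    TuningCurveModel,
    direction_grid,
    simulate_trials,
)


@pytest.fixture
def grid16():
    return direction_grid(16)


@pytest.fixture
def grid4():
    return direction_grid(4)


@pytest.fixture
def ori_grid2():
    return AngleGrid([0.0, 90.0], "orientation")


@pytest.fixture
def tuned_cell(grid16):
    """Strongly tuned direction cell with mild noise, 7 trials."""
    model = TuningCurveModel(c=0.5, r_pref=10.0, r_null=4.0,
                             theta_pref=47.0, sigma=24.0)
    return simulate_trials(model, grid16, 7,
                           NoiseModel("constant_fraction", 0.2), seed=42)


@pytest.fixture
def flat_cell(grid16):
    """Unselective cell (flat 10 Hz) with 40% noise, 7 trials."""
    model = TuningCurveModel(c=10.0, r_pref=0.0, r_null=0.0,
                             theta_pref=0.0, sigma=20.0)
    return simulate_trials(model, grid16, 7,
                           NoiseModel("constant_fraction", 0.4), seed=43)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
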