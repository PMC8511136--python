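import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from irtsim.calibration import FitConfig, Measurement
from irtsim.model_core import ModelParams, evaluate_volumes


@pytest.fixture
def mid_params() -> ModelParams:
    """Mid-range parameter set used across modules."""
    return ModelParams(
        lambda_growth=0.065,
        surviving_fraction=0.41,
        epsilon=9e-4,
        gamma0=0.065,
        V0=10.0,
    )


@pytest.fixture
def fast_fit_config() -> FitConfig:
    """Reduced multistart count to keep the suite fast."""
    return FitConfig(n_starts=6, n_starts_refit=3, seed=0)


@pytest.fixture
def hfsrt_fractions() -> np.ndarray:
    return np.arange(5, dtype=float)


def noise_free_measurements(
    params: ModelParams, fraction_times, days
) -> list[Measurement]:
    vl, vd = evaluate_volumes(params, fraction_times, days)
    return [Measurement(day=float(d), volume=float(v)) for d, v in zip(days, vl + vd)]


@pytest.fixture
def make_noise_free():
    return noise_free_measurements


def random_params(rng: np.random.Generator) -> ModelParams:
    """Parameter draw spanning the fitted ranges."""
    lam = rng.uniform(0.02, 0.13)
    return ModelParams(
        lambda_growth=lam,
        surviving_fraction=rng.uniform(0.05, 0.95),
        epsilon=10.0 ** rng.uniform(-5.3, -1.7),
        gamma0=lam,
        V0=rng.uniform(1.0, 60.0),
    )
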