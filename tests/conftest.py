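import warnings

import numpy as np
import pytest

from growthswitch.config import medium_config, production_config

# background-correction clipping warnings are expected on noisy null signals
warnings.filterwarnings("ignore", message="clipped .* negative")


@pytest.fixture(scope="session")
def ref_config():
    """Noise-free reference M9-glucose calibration."""
    return medium_config("M9-glc", seed=42, noise_abs=0.0, noise_fluo=0.0)


@pytest.fixture(scope="session")
def noisy_config():
    """Reference calibration with the default noise model."""
    return medium_config("M9-glc", seed=42)


@pytest.fixture(scope="session")
def prod_config():
    return production_config(seed=42)


@pytest.fixture(scope="session")
def batch_states(ref_config):
    """Noise-free fully induced batch with latent states attached."""
    from growthswitch.simulate import simulate_batch

    return simulate_batch(
        ref_config, [(0.0, 1000.0)], 1200.0, keep_states=True
    )


@pytest.fixture(scope="session")
def dose_run_seed0():
    """Reference dose-series simulation + full analysis (shared: expensive)."""
    from growthswitch.pipeline import run_dose_pipeline

    return run_dose_pipeline(seed=0)


def ols_normal_equations(t, y):
    """Independent least-squares oracle via explicit normal equations."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]   # slope, intercept
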