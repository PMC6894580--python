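import numpy as np
import pytest

from ibsim import observers


@pytest.fixture(scope="session")
def count_pool() -> np.ndarray:
    """Small shared pool of simulated ground-truth bounce counts."""
    return observers.make_count_pool(n_traces=4, seed=1234)


@pytest.fixture(scope="session")
def clean_noise() -> observers.ReportNoise:
    """Report noise switched off entirely (deterministic reports)."""
    return observers.ReportNoise(
        loc_sigma_px=0.0,
        extrapolation_px=0.0,
        colour_kappa=1e9,
        q_shape=1.0,
        nonnoticer_loc_sigma_px=0.0,
        count_error_sd=0.0,
    )
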