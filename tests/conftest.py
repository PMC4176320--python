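import numpy as np
import pytest

from rcr import ModelParams

#: reference fitted switching rate for phi29 RCA, per second
LAM_FITTED = 1.95e-5


@pytest.fixture
def fitted_params() -> ModelParams:
    """Unit-amplitude parameters at the fitted switching rate."""
    return ModelParams(lam=LAM_FITTED, amplitude=1.0)


@pytest.fixture
def dense_grid() -> np.ndarray:
    """10^3-point time grid covering 0 to 5 half-lives, seconds."""
    return np.linspace(0.0, 5 * np.log(2) / LAM_FITTED, 1000)
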