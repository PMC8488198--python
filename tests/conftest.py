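import numpy as np
import pytest

from sumtwas.model_core import GeneSummaryData, ModelParams


def ar1_matrix(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def model_draw(
    rng: np.random.Generator,
    m: int,
    sigma2: float = 0.5,
    alpha: float = 0.4,
    rho: float = 0.0,
) -> GeneSummaryData:
    """Draw (zhat1, zhat2) exactly from the generative model."""
    R = ar1_matrix(m, rho)
    L = np.linalg.cholesky(R)
    g = np.sqrt(sigma2) * rng.standard_normal(m)
    z1 = R @ g + L @ rng.standard_normal(m)
    z2 = alpha * R @ g + L @ rng.standard_normal(m)
    return GeneSummaryData("g", z1, z2, R, R.copy())


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_data(rng):
    return model_draw(rng, m=4, rho=0.5)


@pytest.fixture
def default_params():
    return ModelParams(sigma2_gamma=0.5, alpha_prime=0.3, tau=1.2)
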