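import numpy as np
import pytest

from expressivity.mine import AttributeVector, FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def gaussian_pair(rho: float, n: int, seed: int = 0):
    """Scalar bivariate Gaussian (F, A) with correlation rho.

    True MI is -0.5*ln(1 - rho^2); the closed form serves as the
    estimator oracle throughout the suite.
    """
    g = np.random.default_rng(seed)
    z = g.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    return (FeatureMatrix(z[:, :1]),
            AttributeVector(z[:, 1], kind="continuous", name=f"rho{rho}"))


@pytest.fixture
def tiny_cohort():
    from expressivity.synthetic_data import CohortConfig, sample_cohort
    return sample_cohort(CohortConfig(n=400, seed=7))
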