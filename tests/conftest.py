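import numpy as np
import pytest
from hypothesis import settings

from tumorperf.config import RunConfig
from tumorperf.geometry import TumorGeometry
from tumorperf.ifp import RadialGrid, TransportParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry() -> TumorGeometry:
    return TumorGeometry()


@pytest.fixture(scope="session")
def transport() -> TransportParams:
    return TransportParams()


@pytest.fixture(scope="session")
def grid(geometry) -> RadialGrid:
    return RadialGrid.uniform(geometry.R_domain, 800)


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


def ols_oracle(x, y):
    """Closed-form simple least squares, independent of the implementation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xb, yb = x.mean(), y.mean()
    sxx = np.sum((x - xb) ** 2)
    sxy = np.sum((x - xb) * (y - yb))
    slope = sxy / sxx
    intercept = yb - slope * xb
    resid = y - intercept - slope * x
    s2 = np.sum(resid**2) / (n - 2)
    se_slope = np.sqrt(s2 / sxx)
    syy = np.sum((y - yb) ** 2)
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    return slope, intercept, r, se_slope
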