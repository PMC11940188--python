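import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ols_oracle(x, y):
    """Closed-form normal-equations least squares (independent oracle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sy * sxx - sx * sxy) / det
    return slope, intercept
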