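import numpy as np
import pytest

import chokinetics as ck


@pytest.fixture(scope="session")
def rcho():
    """Shipped r-CHO 33 C parameter set (table2 source)."""
    return ck.get_default_parameters("r-CHO", 33.0, "table2")


@pytest.fixture(scope="session")
def ncho():
    return ck.get_default_parameters("n-CHO", 33.0, "table2")


@pytest.fixture(scope="session")
def registry():
    return ck.default_registry()


@pytest.fixture()
def exp_series():
    """Noiseless exponential culture: X = 2e5 * exp(0.035 t), S constant."""
    t = np.arange(0.0, 96.0 + 1e-9, 24.0)
    return ck.CultureTimeSeries(
        time=t, X=2e5 * np.exp(0.035 * t), S=np.full_like(t, 4.8)
    )
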