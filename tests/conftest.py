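import numpy as np
import pytest

from midgetkit import synthetic


@pytest.fixture(scope="session")
def off_kernel():
    """Unit-trough OFF kernel with its extremum at 25 ms."""
    return synthetic.off_temporal_kernel(tau_ms=5.0, n=5)


@pytest.fixture(scope="session")
def off_model(off_kernel):
    return synthetic.LNPModel(off_kernel, baseline_rate=20.0, gain=8.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
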