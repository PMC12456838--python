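import numpy as np
import pytest

import gpanet as gp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_gpa_network():
    """Two-point GPA mixture, modest size, below its critical coupling."""
    gc = gp.critical_coupling_two_point(0.5, 1.0, 10.0, 0.5).gc
    return gp.build_network(
        gp.TwoPoint(p=0.5, low=1.0, high=10.0), gp.Constant(0.5), 200, 0.7 * gc, seed=7
    )


@pytest.fixture(scope="session")
def chaotic_network():
    """Same mixture well above the critical coupling."""
    return gp.build_network(
        gp.TwoPoint(p=0.5, low=1.0, high=10.0), gp.Constant(0.5), 200, 1.2, seed=7
    )
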