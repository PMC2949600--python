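import numpy as np
import pytest

from gravfield.gfa_core import MassFunction


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quadratic_1d():
    """1-D bell: maximum 1 at x = 0.3 on [0, 1]."""
    return MassFunction(
        lambda X: -((X[:, 0] - 0.3) ** 2),
        np.array([[0.0, 1.0]]),
        sense="maximize",
        name="bell",
    )


@pytest.fixture
def sphere_2d():
    from gravfield.evaluation import get_benchmark

    return get_benchmark("sphere").mass_function(2, (-2.0, 2.0))
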