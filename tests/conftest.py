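import numpy as np
import pytest

from pathmeasure import ProcessSpec, TimeGrid, make_potential

EPS = 0.5


def process(name: str, eps: float = EPS, **params) -> ProcessSpec:
    return ProcessSpec(make_potential(name, **params), eps)


@pytest.fixture
def grid():
    """Short grid for exact-identity tests."""
    return TimeGrid(dt=0.01, n_steps=50)


@pytest.fixture
def mc_grid():
    """dt=1e-3, T=1: the default Monte-Carlo validation grid."""
    return TimeGrid(dt=1e-3, n_steps=1000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(
    params=[
        ("zero", {}),
        ("linear", {"c": 1.5}),
        ("harmonic", {"A": 2.0}),
        ("double_well", {"h": 5.0, "a": 1.0, "w": 2.0}),
    ],
    ids=["zero", "linear", "harmonic", "double_well"],
)
def any_process(request):
    name, params = request.param
    return process(name, **params)
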