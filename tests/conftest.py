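import numpy as np
import pytest

from neuralpf import StateSpaceModel, model_zoo


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def frog():
    return model_zoo("frog", sigma_v2=0.1, sigma_a2=0.1)


@pytest.fixture
def frog_visual():
    return model_zoo("frog_visual", sigma_v2=0.1, J=1.0)


@pytest.fixture
def ou_1d():
    """Reference 1-D linear model: a=-0.75, unit noises, identity g."""
    return model_zoo("linear_d", d=1)


def make_custom(n=1, m=1, f=None, g=None, sigma_x=None, sigma_y=None):
    """Minimal custom model for hand-computed examples."""
    return StateSpaceModel(
        n=n, m=m,
        f=f if f is not None else (lambda x: np.zeros_like(x)),
        sigma_x=np.zeros((n, n)) if sigma_x is None else sigma_x,
        g=g if g is not None else (lambda x: np.asarray(x, float)[..., :m]),
        sigma_y=np.eye(m) if sigma_y is None else sigma_y,
    )
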