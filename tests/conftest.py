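import numpy as np
import pytest

from crossrbm.rbm import RBMParams


def random_params(rng: np.random.Generator, D: int, H: int, scale: float = 0.5) -> RBMParams:
    """A generic small random model with non-trivial couplings and precisions."""
    return RBMParams(
        W=scale * rng.standard_normal((H, D)),
        b=scale * rng.standard_normal(H),
        c=rng.standard_normal(D),
        lam=np.exp(0.4 * rng.standard_normal(D)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params(rng):
    """D=3, H=2 model, small enough for exact hidden-layer enumeration."""
    return random_params(rng, D=3, H=2)
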