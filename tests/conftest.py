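import numpy as np
import pytest

from dimburst import ModelParams


@pytest.fixture
def p2():
    """Reference 2-D parameter set of the cost-gated regime."""
    return ModelParams(d_max=2, C=1.0, sigma_beta=0.15, b=0.85, sigma_alpha=0.5)


@pytest.fixture
def p1():
    """1-D parameters (no birth-rate penalty applies)."""
    return ModelParams(d_max=1, C=1.0, sigma_beta=0.15, b=0.84, sigma_alpha=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_community_params(rng, d):
    return ModelParams(
        d_max=d,
        C=1.0,
        sigma_beta=float(rng.uniform(0.1, 0.3)),
        b=float(rng.uniform(0.3, 1.0)),
        sigma_alpha=float(rng.uniform(0.3, 1.0)),
    )
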