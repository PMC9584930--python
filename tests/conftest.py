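import numpy as np
import pytest

from traitlearn import make_surrogate
from traitlearn.design import build_design


@pytest.fixture(scope="session")
def exp1_surrogate():
    return make_surrogate("exp1", seed=101)


@pytest.fixture(scope="session")
def exp1_design():
    return build_design("exp1")


@pytest.fixture(scope="session")
def tiny_design():
    """Four items over two factors, 1-8 scale: small enough to hand-step."""
    return build_design(
        {
            "items": {"i1": "A", "i2": "A", "i3": "B", "i4": "B"},
            "scale_min": 1,
            "scale_max": 8,
            "n_profiles": 2,
            "name": "tiny",
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
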