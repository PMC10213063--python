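import numpy as np
import pytest

from epiflat import generate_stack, preset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def eye_stack():
    """One folded stack with ground truth, shared across read-only tests."""
    tissue, signal = preset("eye_wt", seed=7)
    return generate_stack(tissue, signal)


@pytest.fixture(scope="session")
def wing_stack():
    tissue, signal = preset("wing_wt", seed=7)
    return generate_stack(tissue, signal)
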