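import pytest

from syncache import generate_pattern_set


@pytest.fixture(scope="session")
def small_patterns():
    """A comfortably learnable problem (P = N/2)."""
    return generate_pattern_set(100, 50, seed=11)


@pytest.fixture(scope="session")
def square_patterns():
    """P = N: the standard load of the perceptron experiments, desk scale."""
    return generate_pattern_set(200, 200, seed=5)
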