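import numpy as np
import pytest

from cav1net import build_reference_model, compile_network, parse_rules_text


@pytest.fixture(scope="session")
def reference_model():
    return build_reference_model()


@pytest.fixture(scope="session")
def compiled_reference(reference_model):
    return compile_network(reference_model)


@pytest.fixture
def tiny_chain():
    """input E; A copies E; B copies A."""
    return parse_rules_text("input E\nA = E\nB = A\n")


@pytest.fixture
def and_gate():
    """input E1, E2; A = E1 & E2."""
    return parse_rules_text("input E1\ninput E2\nA = E1 & E2\n")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
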