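import numpy as np
import pytest

from cldmd.forcefield import ForceFieldParams, build_chain


@pytest.fixture(scope="session")
def small_model():
    """10-bead mixed-class chain used across engine tests."""
    return build_chain("AKDAGSAKDA")


@pytest.fixture(scope="session")
def hydrophobic_model():
    return build_chain("A" * 30)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams()
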