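import pytest

from gtmsel import CHILD, GTMSpec, VariableId


def X(i: int) -> VariableId:
    return VariableId.active(i)


@pytest.fixture
def spec23() -> GTMSpec:
    """The reference model: two active predictors beyond X_1, gamma = 2/3."""
    return GTMSpec(2, 2.0 / 3.0)


@pytest.fixture
def child() -> VariableId:
    return CHILD
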