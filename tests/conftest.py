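import pytest

from cofactorscope import make_toy_model


@pytest.fixture
def toy1():
    return make_toy_model("TOY1")


@pytest.fixture
def toy1_dup():
    return make_toy_model("TOY1-dup")


@pytest.fixture
def toy1_h():
    return make_toy_model("TOY1-H")
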