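import pytest

import quantumcog as qc


@pytest.fixture
def example() -> qc.QuantumModel:
    """The packaged 2-D prediction/evidence worked example."""
    return qc.example_model()


@pytest.fixture
def ctx_p(example):
    return example.context("P")


@pytest.fixture
def ctx_e(example):
    return example.context("E")
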