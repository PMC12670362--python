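import pytest

from thermodeb import DEBParameters, predict_treatments


@pytest.fixture()
def params() -> DEBParameters:
    return DEBParameters()


@pytest.fixture(scope="session")
def treatment_predictions():
    """Deterministic model predictions for the 16 factorial treatments."""
    return predict_treatments(DEBParameters())
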