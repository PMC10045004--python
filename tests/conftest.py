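import numpy as np
import pytest

from drykin import ParameterSet, eval_model


@pytest.fixture(scope="session")
def cd40_logistic_curve():
    """Noiseless logistic MR curve for the 40 degC convective condition."""
    t = np.arange(0.0, 451.0, 10.0)
    params = ParameterSet("Logistic", {"b": 1.5349, "a": 0.5530, "k": 0.0202})
    return t, np.asarray(eval_model(params, t)), params


@pytest.fixture(scope="session")
def md600_exponential_curve():
    """Noiseless pure-exponential MR curve for the 600 W microwave condition."""
    t = np.arange(0.0, 25.0001, 0.5)
    return t, 1.0101 * np.exp(-0.1535 * t)
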