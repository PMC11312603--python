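import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20110101)


@pytest.fixture
def zero_coefficients():
    from healthequity.simulate import DEFAULT_PROBIT_COEFFICIENTS

    return {k: 0.0 for k in DEFAULT_PROBIT_COEFFICIENTS}
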