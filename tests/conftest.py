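import warnings

import numpy as np
import pytest

# statsmodels mixed-model fits on small simulated datasets emit
# convergence chatter that is part of normal operation here
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
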