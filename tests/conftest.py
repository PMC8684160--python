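import warnings

import numpy as np
import pytest

# latent-model non-convergence within capped iterations is expected on
# small test fixtures and is part of what some tests assert around
warnings.filterwarnings("ignore", message="latent model .* did not converge")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
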