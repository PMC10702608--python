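import numpy as np
import pytest

from mfaunet.network import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def micro_config():
    """Smallest sensible architecture; keeps network tests fast."""
    return ModelConfig(encoder_channels=(4, 8, 16, 32), msam_mlp_ratio=0.5,
                       pam_reduction=2, mbdm_branch_channels=2,
                       head_channels=4, seed=11)


def numgrad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of array ``x``."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
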