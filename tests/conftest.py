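import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pairwise():
    """Random enumerable Potts model, N=4 / q=3."""
    from pairdistill import random_pairwise_model

    return random_pairwise_model(4, 3, coupling_scale=0.4, field_scale=0.7, seed=11)


@pytest.fixture
def tiny_ardca():
    """Random parameterized autoregressive model, N=4 / q=3."""
    from pairdistill.ardca import ArDCA

    g = np.random.default_rng(7)
    return ArDCA.from_parameters(
        h=g.normal(size=(4, 3)), J=g.normal(scale=0.5, size=(4, 4, 3, 3))
    )


@pytest.fixture
def small_vae():
    """Randomly initialized (untrained) VAE, N=5 / q=3."""
    from pairdistill.vae import SequenceVAE

    vae = SequenceVAE(hidden=8, latent=2, seed=5)
    params = vae._init_params(5, 3, np.random.default_rng(9))
    return SequenceVAE.from_parameters(params, N=5, q=3)
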