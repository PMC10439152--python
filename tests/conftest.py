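import numpy as np
import pytest

from lesiongan import nn
from lesiongan.discriminator import DiscriminatorConfig, build_discriminator
from lesiongan.egan import CompoundScalingSpec, EganConfig, build_egan
from lesiongan.fixtures import SceneParams, generate_dataset
from lesiongan.mgan import MganConfig, build_mgan


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Eight 64px synthetic scenes shared across tests."""
    root = tmp_path_factory.mktemp("tiny_ds")
    return generate_dataset(8, SceneParams(image_size=64), 42, root)


@pytest.fixture
def small_egan():
    """Reduced-width EGAN (unscaled skeleton at 1/8 width) for fast forwards."""
    nn.seed(0)
    return build_egan(EganConfig(input_size=64,
                                 scaling=CompoundScalingSpec(phi=0.0)).with_width_scale(0.125))


@pytest.fixture
def small_mgan():
    nn.seed(0)
    return build_mgan(MganConfig(input_size=64).with_width_scale(0.25))


@pytest.fixture
def thin_discriminator():
    """Quarter-width discriminator; geometry (kernels/strides) is unchanged."""
    nn.seed(0)
    return build_discriminator(DiscriminatorConfig().scaled(0.25))


def finite_difference_grad(f, x, eps=1e-2):
    """Central-difference gradient of scalar f at x (shared test helper)."""
    g = np.zeros_like(x, dtype=np.float64)
    flat, gf = x.reshape(-1), g.reshape(-1)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = f(x)
        flat[i] = old - eps
        fm = f(x)
        flat[i] = old
        gf[i] = (fp - fm) / (2 * eps)
    return g
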