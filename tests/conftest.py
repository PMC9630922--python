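import numpy as np
import pytest

from cordmaskvar.phantom import PhantomSpec, StudyConfig, generate_phantom, generate_study


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom with exact tissue means (no noise)."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast phantom spec for Monte-Carlo loops."""
    return PhantomSpec(grid_shape=(32, 32, 6), cord_center=(16.0, 16.0),
                       cord_radii=(4.0, 6.0), noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """A small study bundle on disk (4 raters × 6 datasets × 12 slices)."""
    out = tmp_path_factory.mktemp("study")
    config = StudyConfig.demo(master_seed=11)
    manifest = generate_study(config, out)
    return out, config, manifest


def random_mask_pair(rng, shape=(12, 12, 3), p=0.3):
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    return a, b
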