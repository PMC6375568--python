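import numpy as np
import pytest

from cmrsport import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Noiseless uniform annulus: endo 25 mm, wall 10 mm, 10 x 8 mm slices,
    no trabeculae or papillary muscles. Closed-form volumes are exact."""
    spec = PhantomSpec(noise_sigma=0.0, n_papillary=0, trabecular_fraction=0.0)
    stack, contours, truth = generate_phantom(spec)
    return spec, stack, contours, truth


@pytest.fixture(scope="session")
def trabeculated_phantom():
    """Noiseless asymmetric phantom with trabeculae and papillary muscles:
    wall 10 mm with a 12 mm bump (max 22 mm)."""
    spec = PhantomSpec(
        wall_base=10.0,
        wall_bump_amplitude=12.0,
        trabecular_fraction=0.15,
        noise_sigma=0.0,
        seed=11,
    )
    stack, contours, truth = generate_phantom(spec)
    return spec, stack, contours, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
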