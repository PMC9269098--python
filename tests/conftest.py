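import numpy as np
import pytest

import flipdmd as fd

# Kinetic rate set whose analytic eigenvalues are {-0.005, -0.6342, -0.01577} s^-1;
# used throughout as the validation condition.
VALIDATION_RATES = fd.RateConstants(k1=0.016194, k_m1=0.016194, k2=0.005, k3=0.617582)


@pytest.fixture(scope="session")
def rates():
    return VALIDATION_RATES


@pytest.fixture(scope="session")
def basic_scene():
    return fd.default_scene("basic")


@pytest.fixture(scope="session")
def basic_stack(basic_scene):
    """Noise-free 128x128x300 stack of the static three-aggregate scene."""
    stack, gt = fd.render_stack(basic_scene)
    return stack, gt


@pytest.fixture(scope="session")
def basic_model(basic_stack):
    stack, _ = basic_stack
    return fd.fit(stack, rank=3)


@pytest.fixture(scope="session")
def noisy_stack():
    """Same scene with 2% Gaussian noise (seeded)."""
    scene = fd.default_scene(
        "basic", noise=fd.NoiseParams(model="gaussian", sigma=0.02), seed=11
    )
    stack, gt = fd.render_stack(scene)
    return stack, gt


@pytest.fixture(scope="session")
def region_masks(basic_scene):
    sc = basic_scene
    agg = np.zeros(sc.image_shape, dtype=bool)
    yy, xx = np.mgrid[0 : sc.image_shape[0], 0 : sc.image_shape[1]]
    for a in sc.aggregates:
        agg |= np.hypot(xx - a.center_x, yy - a.center_y) <= a.radius
    return {
        "aggregates": agg,
        "nucleus": sc.nucleus_mask,
        "cytoplasm": sc.cell_mask & ~sc.nucleus_mask & ~agg,
    }
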