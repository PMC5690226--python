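import numpy as np
import pytest

from deformgen.grid import ScalarVolume, VectorField
from deformgen.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_shape():
    return (8, 8, 8)


@pytest.fixture
def anis_spacing():
    return (1.0, 1.0, 2.5)


@pytest.fixture
def ramp_volume():
    """A linear intensity ramp along LR on a 12³ grid of 2 mm spacing."""
    shape = (12, 12, 12)
    x = np.arange(shape[0], dtype=float)
    data = np.broadcast_to(x[:, None, None], shape).copy() * 10.0
    return ScalarVolume(data, spacing=(2.0, 2.0, 2.0))


def smooth_random_field(shape, spacing, magnitude_mm, seed, origin=(0.0, 0.0, 0.0)):
    """Seeded smooth random displacement field with bounded magnitude."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    comps = []
    for _ in range(3):
        c = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        comps.append(c)
    comps = np.stack(comps)
    peak = np.sqrt((comps**2).sum(axis=0)).max()
    comps *= magnitude_mm / max(peak, 1e-12)
    return VectorField(comps[0], comps[1], comps[2], spacing, origin)


@pytest.fixture
def tiny_phantom_spec():
    """A coarse, fast phantom for pipeline-level tests."""
    return PhantomSpec(shape=(32, 32, 24), spacing=(4.0, 4.0, 6.0))
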