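import numpy as np
import pytest

from lipovoid.phantoms import PhantomSpec, dumbbell_truth, gen_bubbles


@pytest.fixture(scope="session")
def dumbbell():
    """Two radius-8 cavities bridged by a radius-3 neck (known answer)."""
    return dumbbell_truth()


@pytest.fixture(scope="session")
def small_bubbles():
    """A small multi-bubble phantom with exact ground truth."""
    spec = PhantomSpec(
        "bubbles", (48, 48, 48), voxel_size_um=16.0,
        radius_params={"dist": "fixed", "radius_um": 4 * 16.0, "count": 6},
        seed=11,
    )
    return gen_bubbles(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
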