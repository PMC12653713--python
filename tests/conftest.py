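import numpy as np
import pytest


@pytest.fixture(scope="session")
def tongue_image():
    """One deterministic 640×640 synthetic tongue scene shared by tests."""
    from tococonet import SyntheticSceneSpec, generate_tongue_image

    return generate_tongue_image(SyntheticSceneSpec(seed=7))


@pytest.fixture(scope="session")
def small_scene():
    """A small (160×160) rendered scene for cheaper per-test image work."""
    from tococonet import SyntheticSceneSpec, generate_tongue_image

    spec = SyntheticSceneSpec(
        canvas_size=(160, 160), center=(80.0, 82.0), axes=(52.0, 66.0), seed=11
    )
    return generate_tongue_image(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rgb(rng, h=24, w=24):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
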