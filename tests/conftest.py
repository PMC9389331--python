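import numpy as np
import pytest

from tomatodet.synthdata import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scene():
    """One deterministic synthetic scene with at least one fruit."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture
def scenes():
    """Ten deterministic scenes across illumination modes."""
    out = []
    for i in range(10):
        mode = ("uniform", "gradient", "low")[i % 3]
        cfg = SceneConfig(illumination=mode, seed=50 + i)
        out.append(generate_scene(cfg))
    return out
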