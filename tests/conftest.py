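import numpy as np
import pytest

from priorcon.synthetic import SceneSpec, generate_dataset

THREE_CLASS_MIX = {"red_lesion": 1 / 3, "pale_bump": 1 / 3, "vascular_streak": 1 / 3}


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """12 synthetic scenes (3 classes) with a manifest, shared across tests."""
    out = tmp_path_factory.mktemp("scenes12")
    manifest = generate_dataset(SceneSpec(seed=11), 12, THREE_CLASS_MIX, out)
    return out, manifest


@pytest.fixture(scope="session")
def scene_red():
    from priorcon.synthetic import generate_scene

    return generate_scene(SceneSpec(seed=1, lesion_class="red_lesion"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_unit(rng, n, d=128):
    z = rng.standard_normal((n, d))
    return z / np.linalg.norm(z, axis=1, keepdims=True)
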