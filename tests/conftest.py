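import numpy as np
import pytest

from coloqc import synthetic
from coloqc.color_features import RegionClass, build_cube


@pytest.fixture(scope="session")
def palette():
    return synthetic.RegionPalette()


@pytest.fixture(scope="session")
def small_cubes(palette):
    """Color cubes from reduced patch libraries (fast; still well-populated)."""
    sizes = {
        RegionClass.MUCOSA: 40,
        RegionClass.RESIDUE: 30,
        RegionClass.LUMEN: 30,
    }
    libs = synthetic.generate_patch_libraries(palette, seed=2024, sizes=sizes)
    return {cls: build_cube(p, cls.name.lower()) for cls, p in libs.items()}


@pytest.fixture(scope="session")
def scene_pair(palette):
    """One synthetic frame with its ground-truth mask."""
    spec = synthetic.SceneSpec(seed=77)
    return synthetic.generate_frame(spec, palette)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
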