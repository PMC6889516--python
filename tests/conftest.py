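import numpy as np
import pytest
import trimesh

from embryoheart.core_io import TrackedSurface


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def icosphere_surface():
    ico = trimesh.creation.icosphere(subdivisions=3)
    return TrackedSurface(
        vertices0=np.asarray(ico.vertices, dtype=float),
        faces=np.asarray(ico.faces),
    )


@pytest.fixture
def small_phantom_spec():
    from embryoheart.phantom import PhantomSpec

    return PhantomSpec(
        grid_shape=(32, 32, 32), spacing=0.045, n_frames=8, noise_seed=7
    )
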