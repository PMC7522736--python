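import numpy as np
import pytest

from qsmtfir import PhantomSpec, ScalarVolume, VoxelGrid, make_brain_phantom


@pytest.fixture
def grid16():
    return VoxelGrid((16, 16, 16))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_volume(grid16, rng):
    return ScalarVolume(grid16, rng.standard_normal(grid16.dims), "generic")


@pytest.fixture(scope="session")
def small_brain():
    """32^3 brain phantom shared by solver/fitting tests."""
    spec = PhantomSpec(grid=VoxelGrid((32, 32, 32)), seed=5)
    chi, r2s, brain, head = make_brain_phantom(spec)
    return {"spec": spec, "chi": chi, "r2s": r2s, "brain": brain, "head": head}
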