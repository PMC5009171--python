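import numpy as np
import pytest

from tractconcord.phantom import PhantomConfig, build_phantom
from tractconcord.tractography import TrackingParams, run_tractography


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def left_map(default_phantom):
    """Full-scale connectivity map (2000 samples per seed voxel)."""
    params = TrackingParams(samples_per_seed_voxel=2000, rng_seed=1)
    return run_tractography(default_phantom, params, side="left")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
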