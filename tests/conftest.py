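import numpy as np
import pytest

from felifat.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(cat_id="fixture", target_fat_fraction=0.30, seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def bimodal_histogram():
    """Histogram of 1e6 voxels drawn from two equal Gaussian tissue modes
    at -100 and +60 HU (sd 10), integer-rounded: modal bins known by
    construction."""
    from felifat.ct import CTVolume, build_histogram

    rng = np.random.default_rng(42)
    fat = rng.normal(-100, 10, 500_000)
    lean = rng.normal(60, 10, 500_000)
    hu = np.rint(np.concatenate([fat, lean])).astype(np.int32)
    vol = CTVolume(hu=hu.reshape(100, 100, 100), spacing=(0.05, 0.05, 0.06))
    return build_histogram(vol, -250, 250)
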