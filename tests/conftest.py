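import numpy as np
import pytest

from strokeperf.io import PipelineConfig
from strokeperf.phantom import Ellipsoid, PhantomSpec, make_phantom
from strokeperf.pipeline import run_ctp_pipeline


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_ds(default_spec):
    """Noiseless full-size CTP phantom (64x64x16x40)."""
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def noiseless_config():
    """Pipeline config tuned for noiseless data: no smoothing, near-exact SVD."""
    return PipelineConfig(fwhm_mm=0.0, threshold_frac=0.01)


@pytest.fixture(scope="session")
def ctp_result(phantom_ds, noiseless_config):
    return run_ctp_pipeline(phantom_ds.series, noiseless_config)


@pytest.fixture(scope="session")
def small_spec():
    """Cheap phantom for tests that only need the shapes to be right."""
    return PhantomSpec(
        grid_shape=(32, 32, 10),
        voxel_size=(6.0, 6.0, 6.0),
        core_region=Ellipsoid((15.5, 13.0, 4.5), (18.0, 18.0, 12.0)),
        penumbra_region=Ellipsoid((15.5, 14.5, 4.5), (34.0, 34.0, 18.0)),
    )


@pytest.fixture(scope="session")
def small_ds(small_spec):
    return make_phantom(small_spec)


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))
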