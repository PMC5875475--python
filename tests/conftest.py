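import numpy as np
import pytest

from ctssp import ROISpec, SimConfig, build_ssp, generate_series


@pytest.fixture
def clean_config():
    """Noise-free 2.5 mm-thickness simulation on the 101-point grid."""
    return SimConfig(true_fwhm=2.88, thickness=2.5, image_size=32, seed=123)


@pytest.fixture
def clean_series(clean_config):
    return generate_series(clean_config)


@pytest.fixture
def center_roi():
    return ROISpec(shape="circle", center=(16, 16), radius=3.0)


@pytest.fixture
def clean_curve(clean_series, center_roi):
    return build_ssp(clean_series, center_roi, "max")


def gaussian_curve(sigma=1.0, interval=0.1, half_width=5.0, mu=0.0, amplitude=1.0, baseline=0.0):
    """Exact Gaussian samples on a symmetric grid (independent of the package)."""
    from ctssp.ssp_core import SSPCurve

    z = np.arange(-half_width, half_width + interval / 2, interval) + mu
    v = amplitude * np.exp(-((z - mu) ** 2) / (2 * sigma**2)) + baseline
    return SSPCurve(z=z, v=v, statistic="max", background=0.0, norm_factor=1.0)
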