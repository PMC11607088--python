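import numpy as np
import pytest

from aoloop import (LensletGeometry, SensorConfig, build_zernike_basis,
                    render_calibration_frame)


@pytest.fixture(scope="session")
def basis63():
    return build_zernike_basis(10, exclude_piston_tip_tilt=True)


@pytest.fixture(scope="session")
def geom():
    return LensletGeometry()


@pytest.fixture(scope="session")
def sensor_cfg():
    return SensorConfig()


@pytest.fixture(scope="session")
def calib_frame(geom, sensor_cfg):
    return render_calibration_frame(geom, sensor_cfg)


@pytest.fixture(scope="session")
def random_wavefront(basis63):
    """A fixed 0.3 um RMS wavefront spread over all 63 modes."""
    from aoloop import WavefrontState
    rng = np.random.default_rng(1)
    c = rng.normal(0.0, 1.0, basis63.mode_count)
    c *= 0.3 / np.linalg.norm(c)
    return WavefrontState(coefficients=c)
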