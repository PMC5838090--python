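import numpy as np
import pytest

from spraymode import AcquisitionGeometry


@pytest.fixture(scope="session")
def reference_geometry() -> AcquisitionGeometry:
    """The recording geometry of the reference device: 5.565 x 3.366 mm
    field of view on 992 x 600 px at 10 kHz, 4 mm working distance."""
    return AcquisitionGeometry(
        fov_width_mm=5.565, fov_height_mm=3.366,
        image_width=992, image_height=600,
        frame_rate_hz=10_000, working_distance_mm=4.0,
        tip_position_px=50.0)


@pytest.fixture(scope="session")
def narrow_geometry() -> AcquisitionGeometry:
    """Same pixel size and frame rate on a narrow 992 x 200 strip —
    cheap to render, same axial physics."""
    return AcquisitionGeometry(
        fov_width_mm=5.565, fov_height_mm=5.565 * 200 / 992,
        image_width=992, image_height=200,
        frame_rate_hz=10_000, working_distance_mm=4.0,
        tip_position_px=50.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
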