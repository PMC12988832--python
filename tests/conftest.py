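import numpy as np
import pytest

from pavis.acquisition import AcquisitionParams, ImageGrid


@pytest.fixture
def small_params() -> AcquisitionParams:
    """8-element toy array for brute-force-checkable beamforming."""
    return AcquisitionParams(
        n_elements=8, pitch_mm=0.09, aperture_width_mm=0.72, n_samples=64
    )


@pytest.fixture
def mid_params() -> AcquisitionParams:
    """64-element array, deep enough for a 10 mm point target."""
    return AcquisitionParams(
        n_elements=64, pitch_mm=0.09, aperture_width_mm=5.76, n_samples=1024
    )


@pytest.fixture
def mid_grid(mid_params) -> ImageGrid:
    return ImageGrid.from_params(mid_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
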