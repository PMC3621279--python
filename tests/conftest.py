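import numpy as np
import pytest

from mbdose import BeamGeometry, DetectorModel, DoseModel, Profile

PRINTED_COEFFS = (240.96, 144.33, -3.3971)  # (c0, c1, c2) of the fluorescence model


@pytest.fixture
def geometry() -> BeamGeometry:
    return BeamGeometry()


@pytest.fixture
def noiseless_fluorescence() -> DetectorModel:
    return DetectorModel.fluorescence(noise_sigma=0.0)


@pytest.fixture
def study_dose_model() -> DoseModel:
    """Realistic study conditions: penumbra + long-range scatter."""
    return DoseModel(
        peak_dose_gy=100.0,
        penumbra_sigma_um=2.0,
        scatter_fraction=0.15,
        scatter_sigma_um=500.0,
    )


def gaussian_profile(sigma_um: float = 10.0, pixel_um: float = 1.25,
                     half_extent_um: float = 100.0, amplitude: float = 1000.0,
                     baseline: float = 0.0) -> Profile:
    """Analytic Gaussian response profile centred mid-extent."""
    x = np.arange(-half_extent_um, half_extent_um + pixel_um / 2, pixel_um)
    v = baseline + amplitude * np.exp(-(x**2) / (2 * sigma_um**2))
    return Profile(positions_um=x - x[0], values=v)
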