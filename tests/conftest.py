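import numpy as np
import pytest

from overinform.staircase import AttributeCalibration, CalibrationResult


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def calibration():
    """A deterministic successful calibration for both attributes."""
    colour = AttributeCalibration(
        label_A="blue", label_B="green",
        high_disc_A=1, high_disc_B=50, low_disc_A=24, low_disc_B=27,
        success=True,
    )
    material = AttributeCalibration(
        label_A="wood", label_B="metal",
        high_disc_A=1, high_disc_B=10, low_disc_A=5, low_disc_B=6,
        success=True,
    )
    return CalibrationResult(attributes={"colour": colour, "material": material})
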