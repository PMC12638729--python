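import numpy as np
import pytest

import vffr1d as v

PA_MMHG = 90.0
PA_SI = PA_MMHG * v.MMHG_TO_PA


@pytest.fixture(scope="session")
def fluid():
    return v.FluidProperties()


@pytest.fixture(scope="session")
def tapered_profile():
    """Unstenosed smooth taper at reconstruction scales (1.35 -> 0.95 mm radius)."""
    return v.generate_vessel(v.VesselSpec(length_mm=30.0, r_in_mm=1.35, r_out_mm=0.95))


@pytest.fixture(scope="session")
def tapered_segmentation(tapered_profile):
    return v.estimate_and_segment(tapered_profile)


@pytest.fixture(scope="session")
def uniform_profile():
    return v.generate_vessel(v.VesselSpec(length_mm=20.0, r_in_mm=1.5, r_out_mm=1.5))


@pytest.fixture(scope="session")
def uniform_segmentation(uniform_profile):
    return v.estimate_and_segment(uniform_profile)


@pytest.fixture(scope="session")
def stenosed_profile():
    """Tapered vessel with one focal 50% diameter stenosis."""
    return v.generate_vessel(v.VesselSpec(
        length_mm=30.0, r_in_mm=1.35, r_out_mm=0.95,
        stenoses=(v.Stenosis(centre_frac=0.5, severity=0.5, width_mm=1.5),),
    ))


@pytest.fixture(scope="session")
def stenosed_segmentation(stenosed_profile):
    return v.estimate_and_segment(stenosed_profile)


def identity_segmentation(profile):
    """Segmentation that takes the raw radii as the healthy lumen."""
    return v.HealthySegmentation.all_healthy(profile)
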