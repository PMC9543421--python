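import numpy as np
import pytest

from corneatilt.geometry import ConicoidSurface
from corneatilt.raytrace import CornealModel
from corneatilt.synthetic import calibrate_cohort_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gullstrand_model():
    """Untilted rotationally symmetric two-surface cornea (spherical)."""
    anterior = ConicoidSurface.symmetric(7.8, 0.0)
    posterior = ConicoidSurface.symmetric(6.5, 0.0, apex_z=0.55)
    return CornealModel(anterior, posterior)


@pytest.fixture(scope="session")
def paper_model():
    """Cohort model calibrated to the published cohort statistics."""
    return calibrate_cohort_model()
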