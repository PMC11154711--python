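import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from foldscape import fcs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def printed_calibration():
    """The instrument calibration as printed: r = 235 nm, Rh6G reference."""
    return fcs.Calibration(
        lateral_radius=235e-9,
        aspect_ratio=5.0,
        effective_volume=0.56e-15,
        reference_diffusion_coefficient=4.14e-10,
        reference_tau_d=33.35e-6,
    )


@pytest.fixture(scope="session")
def lag_grid():
    """A multi-tau-like lag grid spanning 6.5 decades."""
    return np.logspace(-6.5, 0, 250)
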