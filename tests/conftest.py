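import numpy as np
import pytest

from scalespec import ScenePhysics, WavelengthAxis, simulate_dataset, trim_to_analysis_range


@pytest.fixture(scope="session")
def axis():
    return WavelengthAxis.default()


@pytest.fixture(scope="session")
def quiet_physics():
    """No scatter, baseline or noise: spectra are exact mixtures."""
    return ScenePhysics(scatter_slope_sd=0.0, baseline_sd=0.0, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def region_dataset(axis):
    """A default-conditions 100-sample region dataset on the analysis range."""
    return trim_to_analysis_range(simulate_dataset(100, axis, ScenePhysics(seed=1)))
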