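import numpy as np
import pytest

from pdus import (
    AcquisitionGeometry,
    GroundTruthSpec,
    default_rois,
    simulate_ensemble,
    small_geometry,
)


@pytest.fixture(scope="session")
def geom():
    """Full default geometry: 2.4 x 3.6 mm field at 24 MHz."""
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def small_geom():
    """Cheap ~1.2 x 1.2 mm field for tests that only need realistic speckle."""
    return small_geometry()


@pytest.fixture(scope="session")
def rois(geom):
    return default_rois(geom)


@pytest.fixture(scope="session")
def small_rois(small_geom):
    return default_rois(small_geom)


@pytest.fixture(scope="session")
def moving_ensemble(geom):
    """Default study conditions: 0.010 mm respiration, 15 dB echo SNR."""
    return simulate_ensemble(GroundTruthSpec(seed=11), geom)


@pytest.fixture(scope="session")
def static_ensemble(small_geom):
    """Motionless tissue + blood + noise, small field."""
    spec = GroundTruthSpec(
        respiration_amplitude_mm=0.0, axial_drift_mm_per_s=0.0, seed=5
    )
    return simulate_ensemble(spec, small_geom)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
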