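import numpy as np
import pytest

from gridsight.camera import default_rig
from gridsight.detection import ClassicalDetector
from gridsight.evaluation import ClassicalPoseEstimator
from gridsight.grid import GridSpec
from gridsight.render import RenderSettings, render_stereo
from gridsight.scenes import make_measurement_scenes


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def scenes():
    """The default 30-position measurement grid."""
    return make_measurement_scenes()


@pytest.fixture(scope="session")
def scene40(scenes):
    """The reference scene: grid facing the camera at 40 cm."""
    return next(s for s in scenes if s.is_reference)


@pytest.fixture(scope="session")
def clean_settings():
    """Noise-free, blur-free, flat-lit render settings (exact appearance)."""
    return RenderSettings(
        noise_sigma=0.0, blur_sigma=0.0, background_mode="flat",
        background_range=(0.15, 0.15), ambient=1.0,
        disk_sigma=0.0, sheet_sigma=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def stereo40(rig, scene40):
    """A default-noise stereo pair of the 40 cm reference scene."""
    return render_stereo(rig, scene40.state, RenderSettings(seed=21))


@pytest.fixture(scope="session")
def stereo40_clean(rig, scene40, clean_settings):
    return render_stereo(rig, scene40.state, clean_settings)


@pytest.fixture(scope="session")
def detector():
    return ClassicalDetector()


@pytest.fixture(scope="session")
def pose_estimator():
    return ClassicalPoseEstimator(seed=3)


@pytest.fixture(scope="session")
def grid_spec():
    return GridSpec()


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    from gridsight.fixtures import make_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    manifest = make_fixtures(out, seed=7)
    return out, manifest
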