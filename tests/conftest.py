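import numpy as np
import pytest

from sowscope.calibration import CameraCalibration, ScaleCalibration
from sowscope.depth_io import DepthFrame
from sowscope.morphometry import SideGeometry
from sowscope import synth_scene as ss


@pytest.fixture(scope="session")
def top_rig():
    return ss.default_top_rig()


@pytest.fixture(scope="session")
def side_rig():
    return ss.default_side_rig()


@pytest.fixture(scope="session")
def side_geom(side_rig):
    return SideGeometry(
        focal_length=side_rig.focal_length,
        principal_row=side_rig.principal_point[0],
        cam_height=side_rig.cam_height,
        distance=side_rig.standoff,
    )


@pytest.fixture(scope="session")
def top_cal(top_rig):
    return CameraCalibration(focal_length=top_rig.focal_length)


@pytest.fixture(scope="session")
def side_cal(side_rig):
    return ScaleCalibration(
        scale_factor=side_rig.standoff * 100.0 / side_rig.focal_length
    )


@pytest.fixture(scope="session")
def scene():
    """A centred, yaw-free animal with round-number geometry."""
    return ss.SceneTruth(
        pig_id="pig_ref",
        semi_length=45.0,
        semi_width=16.0,
        semi_height=13.0,
        clearance=25.0,
        center_xy=(0.0, 0.0),
        yaw_deg=0.0,
        true_weight=60.0,
    )


@pytest.fixture(scope="session")
def top_frame(scene, top_rig):
    return ss.render_depth(scene, top_rig)


@pytest.fixture(scope="session")
def side_frame(scene, side_rig):
    return ss.render_depth(scene, side_rig)


@pytest.fixture
def constant_frame():
    """A flat 1.400 m field (1400 counts everywhere)."""
    return DepthFrame(counts=np.full((120, 160), 1400, dtype=np.uint16))
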