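import numpy as np
import pytest

from agrotrack.geometry import CameraIntrinsics, RigidPose
from agrotrack.instances import DepthImage, InstanceMask
from agrotrack.tracking import CameraRig


@pytest.fixture
def K():
    return CameraIntrinsics(fx=500.0, fy=500.0, cx=320.0, cy=240.0,
                            width=640, height=480)


@pytest.fixture
def rig(K):
    return CameraRig(intrinsics=K, extrinsics=RigidPose.identity())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def square_mask(u0, v0, size, **kwargs):
    """Axis-aligned size x size square with top-left corner (u0, v0)."""
    vv, uu = np.mgrid[v0:v0 + size, u0:u0 + size]
    return InstanceMask(pixels=np.stack([uu.ravel(), vv.ravel()], axis=1),
                        **kwargs)


def uniform_depth(K, depth):
    return DepthImage(np.full((K.height, K.width), depth))


@pytest.fixture
def make_square():
    return square_mask


@pytest.fixture
def make_depth():
    return uniform_depth
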