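"""On-disk dataset formats.

A dataset directory contains::

    intrinsics.yaml      fx, fy, cx, cy, width, height, extrinsics (4x4)
    odometry.jsonl       one record per frame: frame_id, timestamp_s, T (4x4)
    annotations.json     COCO-style instance annotations (RLE masks)
    depth/frame_XXXXXX.png   16-bit PNG, millimeters, 0 = invalid
    manifest.csv         per-row visual ground-truth counts (optional)
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .geometry import CameraIntrinsics, RigidPose
from .instances import DepthImage, InstanceMask, load_annotations, save_annotations
from .tracking import CameraRig, FrameRecord

__all__ = [
    "write_rig",
    "read_rig",
    "write_odometry",
    "read_odometry",
    "write_depth",
    "read_depth",
    "write_dataset",
    "read_dataset",
]


def write_rig(path, rig: CameraRig) -> None:
    doc = rig.intrinsics.to_dict()
    doc["extrinsics"] = [float(x) for x in rig.extrinsics.matrix().flatten()]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def read_rig(path) -> CameraRig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    K = CameraIntrinsics.from_dict(doc)
    E = RigidPose.from_matrix(np.asarray(doc["extrinsics"], dtype=float))
    return CameraRig(intrinsics=K, extrinsics=E)


def write_odometry(path, poses: dict[int, RigidPose],
                   timestamps: dict[int, float] | None = None) -> None:
    with open(path, "w") as fh:
        for frame_id in sorted(poses):
            rec = {
                "frame_id": frame_id,
                "timestamp_s": (timestamps or {}).get(frame_id, 0.0),
                "T": [float(x) for x in poses[frame_id].matrix().flatten()],
            }
            fh.write(json.dumps(rec) + "\n")


def read_odometry(path) -> dict[int, RigidPose]:
    poses: dict[int, RigidPose] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            poses[int(rec["frame_id"])] = RigidPose.from_matrix(
                np.asarray(rec["T"], dtype=float))
    return poses


def write_depth(path, depth: DepthImage) -> None:
    """Write metric depth as 16-bit millimeter PNG (0 stays invalid)."""
    mm = np.clip(np.rint(depth.values * 1000.0), 0, 65535).astype(np.uint16)
    iio.imwrite(path, mm, extension=".png")


def read_depth(path) -> DepthImage:
    mm = iio.imread(path)
    return DepthImage(mm.astype(float) / 1000.0)


def write_dataset(directory, frames: list[FrameRecord], rig: CameraRig,
                  super_classes: tuple[str, ...] = ("object",),
                  sub_classes: tuple[str, ...] = ()) -> Path:
    """Write a frame sequence as a dataset directory; returns the path."""
    root = Path(directory)
    (root / "depth").mkdir(parents=True, exist_ok=True)
    write_rig(root / "intrinsics.yaml", rig)
    write_odometry(root / "odometry.jsonl",
                   {f.frame_id: f.pose for f in frames if f.pose is not None},
                   {f.frame_id: f.timestamp_s for f in frames})
    size = (rig.intrinsics.width, rig.intrinsics.height)
    save_annotations(root / "annotations.json",
                     {f.frame_id: f.detections for f in frames},
                     image_size=size, super_classes=super_classes,
                     sub_classes=sub_classes)
    for f in frames:
        if f.depth is not None:
            write_depth(root / "depth" / f"frame_{f.frame_id:06d}.png", f.depth)
    return root


def read_dataset(directory,
                 sub_class_vocabulary: tuple[str, ...] | None = None
                 ) -> tuple[list[FrameRecord], CameraRig]:
    """Load a dataset directory back into frame records and a camera rig."""
    root = Path(directory)
    rig = read_rig(root / "intrinsics.yaml")
    odometry_path = root / "odometry.jsonl"
    poses = read_odometry(odometry_path) if odometry_path.exists() else {}
    per_frame = load_annotations(root / "annotations.json",
                                 sub_class_vocabulary)
    frames: list[FrameRecord] = []
    for frame_id in sorted(per_frame):
        depth_path = root / "depth" / f"frame_{frame_id:06d}.png"
        depth = read_depth(depth_path) if depth_path.exists() else None
        frames.append(FrameRecord(frame_id=frame_id,
                                  detections=per_frame[frame_id],
                                  depth=depth, pose=poses.get(frame_id)))
    return frames, rig
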