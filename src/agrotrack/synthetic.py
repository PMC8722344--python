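"""Synthetic robot-traverse simulator.

Generates row-traverse sequences — per-frame instance masks, registered
depth, wheel odometry, and a ground-truth manifest — with the structure of
the two target settings:

* ``"field"`` mode: a downward-facing camera over a ground plane carrying
  many small objects with skewed class frequencies;
* ``"wall"`` mode: a sideways-facing camera in front of a crop wall, with a
  second (distractor) object layer beyond a metric depth boundary.

A detector-corruption model (dropout, jitter, morphological perturbation,
spurious instances, label flips) degrades the clean detections so the
tracker and metrics can be stressed without any recorded data.
All randomness flows from explicit integer seeds; a fixed seed reproduces
scenes, frames, and corruptions exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.morphology import dilation, disk, erosion

from .geometry import CameraIntrinsics, RigidPose
from .instances import DepthImage, DepthWindow, InstanceMask
from .tracking import CameraRig, FrameRecord

__all__ = [
    "SceneSpec",
    "TraverseSpec",
    "CorruptionSpec",
    "SceneObject",
    "Scene",
    "GroundTruthManifest",
    "generate_scene",
    "render_sequence",
    "corrupt_detections",
    "PackingError",
]

# skewed default frequency vectors, mirroring strongly imbalanced training
# distributions (field: crop-dominant with rare weeds; wall: green-dominant)
FIELD_FREQUENCIES = {
    "SB": 0.27, "Ch": 0.07, "Th": 0.22, "Bi": 0.11,
    "Pe": 0.22, "Uk": 0.08, "Cy": 0.016, "An": 0.014,
}
WALL_FREQUENCIES = {"Rd": 0.045, "Yl": 0.09, "Gn": 0.78, "Mr": 0.028,
                    "My": 0.057}


class PackingError(RuntimeError):
    """Raised when objects cannot be placed within the overlap budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Static description of one synthetic row."""

    mode: str = "field"  # "field" | "wall"
    n_objects: int = 10
    size_range: tuple[int, int] = (12, 30)  # object pixel extent at its depth
    frequencies: dict[str, float] | None = None
    object_depth: float = 0.8  # field: camera-to-ground; wall: near layer
    distractor_depth: float = 1.3  # wall mode only; beyond the rail boundary
    n_distractors: int = 0
    background_depth: float | None = None  # None -> object/distractor depth
    row_length_m: float = 2.0
    image_size: tuple[int, int] = (320, 240)
    fx: float = 400.0
    fy: float = 400.0
    depth_hole_rate: float = 0.0
    max_overlap: float = 0.0  # allowed bounding-circle overlap fraction

    def __post_init__(self) -> None:
        if self.mode not in ("field", "wall"):
            raise ValueError("mode must be 'field' or 'wall'")
        if self.object_depth <= 0:
            raise ValueError("depths must be positive")
        if self.mode == "wall" and self.distractor_depth <= self.object_depth:
            raise ValueError("distractor layer must lie beyond the near layer")
        freqs = self.frequencies
        if freqs is None:
            freqs = FIELD_FREQUENCIES if self.mode == "field" else WALL_FREQUENCIES
            object.__setattr__(self, "frequencies", dict(freqs))
        elif abs(sum(freqs.values()) - 1.0) > 1e-6:
            raise ValueError("sub-class frequencies must sum to 1")

    @property
    def intrinsics(self) -> CameraIntrinsics:
        w, h = self.image_size
        return CameraIntrinsics(fx=self.fx, fy=self.fy,
                                cx=w / 2.0, cy=h / 2.0, width=w, height=h)

    @property
    def super_class(self) -> str:
        return "plant" if self.mode == "field" else "sweet_pepper"


@dataclass(frozen=True)
class TraverseSpec:
    """Camera motion along the travel (x) axis."""

    speed: float = 0.01  # meters per frame
    n_frames: int = 100
    x_start: float = 0.0
    odometry_noise: float = 0.0  # std of per-frame recorded-pose perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed < 0 or self.n_frames < 1:
            raise ValueError("speed must be >= 0 and n_frames >= 1")

    @classmethod
    def covering(cls, spec: SceneSpec, speed: float, margin_m: float = 0.05,
                 **kwargs) -> "TraverseSpec":
        """A traverse whose camera sweeps the whole row and then some."""
        K = spec.intrinsics
        half_view = (K.width / 2.0) * spec.object_depth / K.fx
        x_start = -half_view - margin_m
        span = spec.row_length_m + 2 * (half_view + margin_m)
        n_frames = max(2, int(math.ceil(span / speed)) + 1) if speed > 0 else 2
        return cls(speed=speed, n_frames=n_frames, x_start=x_start, **kwargs)


@dataclass(frozen=True)
class CorruptionSpec:
    """Detector degradation model."""

    dropout: float = 0.0  # per object per frame
    jitter_std: float = 0.0  # pixels
    morph_range: tuple[int, int] = (0, 0)  # radius; negative erodes
    spurious_rate: float = 0.0  # expected spurious instances per frame
    flip_probability: float = 0.0  # sub-class label flips

    def __post_init__(self) -> None:
        for p in (self.dropout, self.flip_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.jitter_std < 0 or self.spurious_rate < 0:
            raise ValueError("jitter_std and spurious_rate must be >= 0")


@dataclass(frozen=True)
class SceneObject:
    id: int
    sub_class: str
    depth: float
    layer: str  # "near" | "distractor"
    x: float  # world position, meters (plane coordinates)
    y: float
    template: np.ndarray  # boolean stamp, (h, w)
    area_m2: float  # Σ template pixels · d² / (fx·fy), by construction

    @property
    def extent_px(self) -> int:
        return max(self.template.shape)


@dataclass(frozen=True)
class Scene:
    spec: SceneSpec
    objects: tuple[SceneObject, ...]
    seed: int

    def near_objects(self) -> list[SceneObject]:
        return [o for o in self.objects if o.layer == "near"]


@dataclass
class GroundTruthManifest:
    """True counts, areas and per-frame instance ids of a rendered row."""

    scene: Scene
    frame_instances: list[dict[int, np.ndarray]]  # per frame: object id -> pixels

    def counts(self, depth_window: DepthWindow | None = None
               ) -> dict[str, int]:
        """True per-sub-class counts, restricted by an optional depth window."""
        out: dict[str, int] = {}
        for o in self.scene.objects:
            if depth_window is not None and not (
                    depth_window.tau_l <= o.depth <= depth_window.tau_h):
                continue
            out[o.sub_class] = out.get(o.sub_class, 0) + 1
        return out

    def total(self, depth_window: DepthWindow | None = None) -> int:
        return sum(self.counts(depth_window).values())

    def areas_m2(self) -> dict[int, float]:
        return {o.id: o.area_m2 for o in self.scene.objects}


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _ellipse_template(a_px: float, b_px: float, theta: float) -> np.ndarray:
    """Boolean stamp of a rotated ellipse sampled at pixel centers."""
    r = int(math.ceil(max(a_px, b_px))) + 1
    dv, du = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    ct, st = math.cos(theta), math.sin(theta)
    xr = du * ct + dv * st
    yr = -du * st + dv * ct
    stamp = (xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0
    # trim all-empty borders so the template is tight
    rows = np.any(stamp, axis=1)
    cols = np.any(stamp, axis=0)
    return stamp[rows][:, cols]


def _place_layer(rng: np.random.Generator, spec: SceneSpec, n: int,
                 depth: float, layer: str, start_id: int,
                 labels: list[str]) -> list[SceneObject]:
    K = spec.intrinsics
    placed: list[SceneObject] = []
    # lateral span keeping objects projectable inside the image
    max_half_extent_px = spec.size_range[1] / 2 + 2
    y_half = (K.height / 2 - max_half_extent_px - 2) * depth / K.fy
    if y_half <= 0:
        raise PackingError("objects too large for the image height")
    for i in range(n):
        lo, hi = spec.size_range
        for _ in range(200):
            a = rng.uniform(lo, hi) / 2.0
            b = rng.uniform(lo, hi) / 2.0
            theta = rng.uniform(0, math.pi)
            x = rng.uniform(0, spec.row_length_m)
            y = rng.uniform(-y_half, y_half)
            r_m = max(a, b) * depth / K.fx  # bounding radius, meters
            ok = True
            for other in placed:
                r_o = max(other.template.shape) / 2 * other.depth / K.fx
                min_sep = (r_m + r_o) * (1.0 - spec.max_overlap)
                if math.hypot(x - other.x, y - other.y) < min_sep:
                    ok = False
                    break
            if ok:
                break
        else:
            raise PackingError(
                f"could not place object {start_id + i} within the overlap "
                "budget; reduce n_objects or sizes")
        template = _ellipse_template(a, b, theta)
        area = float(template.sum()) * depth ** 2 / (K.fx * K.fy)
        placed.append(SceneObject(
            id=start_id + i, sub_class=labels[i], depth=depth, layer=layer,
            x=x, y=y, template=template, area_m2=area))
    return placed


def generate_scene(spec: SceneSpec, seed: int = 0) -> Scene:
    """Sample a static scene: object ids, positions, shapes, depths, labels."""
    rng = np.random.default_rng(seed)
    names = sorted(spec.frequencies)
    probs = np.array([spec.frequencies[n] for n in names])
    probs = probs / probs.sum()
    objects: list[SceneObject] = []
    if spec.n_objects:
        labels = [str(s) for s in rng.choice(names, size=spec.n_objects, p=probs)]
        objects += _place_layer(rng, spec, spec.n_objects, spec.object_depth,
                                "near", 0, labels)
    if spec.mode == "wall" and spec.n_distractors:
        labels = [str(s) for s in
                  rng.choice(names, size=spec.n_distractors, p=probs)]
        objects += _place_layer(rng, spec, spec.n_distractors,
                                spec.distractor_depth, "distractor",
                                spec.n_objects, labels)
    return Scene(spec=spec, objects=tuple(objects), seed=seed)


# ---------------------------------------------------------------------------
# sequence rendering
# ---------------------------------------------------------------------------

def _stamp_bounds(obj: SceneObject, tx: float, K: CameraIntrinsics):
    """Integer paste window of an object's template for camera position tx."""
    u_c = K.fx * (obj.x - tx) / obj.depth + K.cx
    v_c = K.fy * obj.y / obj.depth + K.cy
    th, tw = obj.template.shape
    # round the projected center so the stamp translates rigidly (no
    # resampling): pixel counts, hence areas, are identical in every frame
    u0 = int(round(u_c)) - tw // 2
    v0 = int(round(v_c)) - th // 2
    return u0, v0, tw, th


def render_sequence(scene: Scene, traverse: TraverseSpec
                    ) -> tuple[list[FrameRecord], GroundTruthManifest, CameraRig]:
    """Render a traverse: per-frame masks, depth, odometry + manifest.

    Objects are painted far-to-near, so near-layer objects occlude
    distractors.  Depth images carry object depths over a background at the
    configured background depth, with i.i.d. invalid holes when requested.
    """
    spec = scene.spec
    K = spec.intrinsics
    w, h = spec.image_size
    rng = np.random.default_rng(traverse.seed)
    bg_depth = spec.background_depth
    if bg_depth is None:
        bg_depth = (spec.object_depth if spec.mode == "field"
                    else spec.distractor_depth + 0.5)
    order = sorted(scene.objects, key=lambda o: -o.depth)  # far first

    frames: list[FrameRecord] = []
    frame_instances: list[dict[int, np.ndarray]] = []
    for f in range(traverse.n_frames):
        tx = traverse.x_start + traverse.speed * f
        label_img = np.full((h, w), -1, dtype=np.int32)
        depth_img = np.full((h, w), bg_depth, dtype=float)
        for obj in order:
            u0, v0, tw, th = _stamp_bounds(obj, tx, K)
            uo0, vo0 = max(u0, 0), max(v0, 0)
            uo1, vo1 = min(u0 + tw, w), min(v0 + th, h)
            if uo0 >= uo1 or vo0 >= vo1:
                continue
            sub = obj.template[vo0 - v0:vo1 - v0, uo0 - u0:uo1 - u0]
            label_img[vo0:vo1, uo0:uo1][sub] = obj.id
            depth_img[vo0:vo1, uo0:uo1][sub] = obj.depth
        if spec.depth_hole_rate > 0:
            holes = rng.random((h, w)) < spec.depth_hole_rate
            depth_img[holes] = 0.0
        detections: list[InstanceMask] = []
        instances: dict[int, np.ndarray] = {}
        for obj in scene.objects:
            vs, us = np.nonzero(label_img == obj.id)
            if vs.size == 0:
                continue
            pixels = np.stack([us, vs], axis=1)
            instances[obj.id] = pixels
            detections.append(InstanceMask(
                pixels=pixels, super_class=spec.super_class,
                sub_class=obj.sub_class, confidence=1.0, image_size=(w, h)))
        noise = (rng.normal(0.0, traverse.odometry_noise, size=3)
                 if traverse.odometry_noise > 0 else np.zeros(3))
        pose = RigidPose(translation=np.array([tx, 0.0, 0.0]) + noise)
        frames.append(FrameRecord(frame_id=f, detections=detections,
                                  depth=DepthImage(depth_img), pose=pose,
                                  timestamp_s=f * 0.1))
        frame_instances.append(instances)
    manifest = GroundTruthManifest(scene=scene, frame_instances=frame_instances)
    return frames, manifest, CameraRig(intrinsics=K)


# ---------------------------------------------------------------------------
# detector corruption
# ---------------------------------------------------------------------------

def _perturb_mask(mask: InstanceMask, rng: np.random.Generator,
                  corruption: CorruptionSpec,
                  image_size: tuple[int, int]) -> InstanceMask | None:
    w, h = image_size
    pixels = mask.pixels
    if corruption.jitter_std > 0:
        shift = np.rint(rng.normal(0.0, corruption.jitter_std, size=2))
        pixels = pixels + shift.astype(np.int64)
    lo, hi = corruption.morph_range
    radius = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    if radius != 0 and len(pixels):
        keep = ((pixels[:, 0] >= 0) & (pixels[:, 0] < w)
                & (pixels[:, 1] >= 0) & (pixels[:, 1] < h))
        binary = np.zeros((h, w), dtype=bool)
        px = pixels[keep]
        if len(px) == 0:
            return None
        binary[px[:, 1], px[:, 0]] = True
        footprint = disk(abs(radius))
        binary = (dilation(binary, footprint) if radius > 0
                  else erosion(binary, footprint))
        vs, us = np.nonzero(binary)
        pixels = np.stack([us, vs], axis=1)
    else:
        keep = ((pixels[:, 0] >= 0) & (pixels[:, 0] < w)
                & (pixels[:, 1] >= 0) & (pixels[:, 1] < h))
        pixels = pixels[keep]
    if len(pixels) == 0:
        return None
    return InstanceMask(pixels=pixels, super_class=mask.super_class,
                        sub_class=mask.sub_class, confidence=mask.confidence,
                        image_size=image_size)


def corrupt_detections(frames: list[FrameRecord], corruption: CorruptionSpec,
                       seed: int, vocabulary: tuple[str, ...] | None = None,
                       image_size: tuple[int, int] | None = None
                       ) -> list[FrameRecord]:
    """Degrade the detection stream; depth/odometry/manifest stay untouched.

    Applies, in order: per-object dropout, centroid jitter, morphological
    dilation/erosion, sub-class flips, and spurious instances (uniformly
    placed random ellipses with random labels and confidences).
    """
    rng = np.random.default_rng(seed)
    out: list[FrameRecord] = []
    for frame in frames:
        if image_size is not None:
            size = image_size
        elif frame.depth is not None:
            size = (frame.depth.shape[1], frame.depth.shape[0])
        elif frame.detections and frame.detections[0].image_size:
            size = frame.detections[0].image_size
        else:
            size = (640, 480)
        vocab = vocabulary
        if vocab is None:
            vocab = tuple(sorted({m.sub_class for m in frame.detections})) or ("Uk",)
        detections: list[InstanceMask] = []
        for mask in frame.detections:
            if corruption.dropout > 0 and rng.random() < corruption.dropout:
                continue
            m = _perturb_mask(mask, rng, corruption, size)
            if m is None:
                continue
            if (corruption.flip_probability > 0 and len(vocab) > 1
                    and rng.random() < corruption.flip_probability):
                others = [s for s in vocab if s != m.sub_class]
                m = replace(m, sub_class=str(rng.choice(others)))
            detections.append(m)
        n_spurious = (int(rng.poisson(corruption.spurious_rate))
                      if corruption.spurious_rate > 0 else 0)
        for _ in range(n_spurious):
            a = rng.uniform(4, 12)
            b = rng.uniform(4, 12)
            template = _ellipse_template(a, b, rng.uniform(0, math.pi))
            th, tw = template.shape
            u0 = int(rng.integers(0, max(1, size[0] - tw)))
            v0 = int(rng.integers(0, max(1, size[1] - th)))
            vs, us = np.nonzero(template)
            detections.append(InstanceMask(
                pixels=np.stack([us + u0, vs + v0], axis=1),
                super_class=(frame.detections[0].super_class
                             if frame.detections else "object"),
                sub_class=str(rng.choice(list(vocab))),
                confidence=float(rng.uniform(0.3, 1.0)),
                image_size=size))
        out.append(FrameRecord(frame_id=frame.frame_id, detections=detections,
                               depth=frame.depth, pose=frame.pose,
                               timestamp_s=frame.timestamp_s))
    return out
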