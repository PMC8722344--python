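"""Instance-mask data model, annotation I/O, per-mask geometry and area.

An :class:`InstanceMask` is a set of integer ``(u, v)`` pixel coordinates
plus a coarse super-class label, a fine-grained sub-class label, and a
detector confidence.  Depth images are metric (meters) with 0 marking
invalid pixels, registered to the RGB frame.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import CameraIntrinsics, FrameTransform, reproject_mask

__all__ = [
    "SB20_SUBCLASSES",
    "BUP20_SUBCLASSES",
    "InstanceMask",
    "DepthImage",
    "MaskGeometry",
    "CaliperMeasurement",
    "DepthWindow",
    "EmptyMaskError",
    "VocabularyError",
    "mask_geometry",
    "estimate_area",
    "depth_inlier_percentage",
    "fov_filter",
    "caliper_bounds",
    "reproject_instance",
    "load_annotations",
    "save_annotations",
    "encode_rle",
    "decode_rle",
    "rasterize_polygons",
]

# Canonical sub-class vocabularies (dataset label sets are configuration).
SB20_SUBCLASSES = ("SB", "Ch", "Th", "Bi", "Pe", "Uk", "Cy", "An")
BUP20_SUBCLASSES = ("Rd", "Yl", "Gn", "Mr", "My")


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty mask."""


class VocabularyError(ValueError):
    """Raised when a sub-class label is not in the configured vocabulary."""


@dataclass
class InstanceMask:
    """One segmented object in one frame.

    ``pixels`` is an (N, 2) integer array of unique (u, v) coordinates.
    """

    pixels: np.ndarray
    super_class: str = "object"
    sub_class: str = ""
    confidence: float = 1.0
    image_size: tuple[int, int] | None = None  # (width, height)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        self.pixels = px
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.image_size is not None and len(px):
            w, h = self.image_size
            if (px[:, 0].min() < 0 or px[:, 0].max() >= w
                    or px[:, 1].min() < 0 or px[:, 1].max() >= h):
                raise ValueError("mask pixels fall outside image bounds")

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def is_empty(self) -> bool:
        return len(self.pixels) == 0

    @classmethod
    def from_binary(cls, binary: np.ndarray, **kwargs) -> "InstanceMask":
        """Build from a boolean (H, W) image; rows are v, columns are u."""
        v, u = np.nonzero(np.asarray(binary, dtype=bool))
        kwargs.setdefault("image_size", (binary.shape[1], binary.shape[0]))
        return cls(pixels=np.stack([u, v], axis=1), **kwargs)

    def to_binary(self, image_size: tuple[int, int] | None = None) -> np.ndarray:
        size = image_size or self.image_size
        if size is None:
            raise ValueError("image_size required to rasterize the mask")
        w, h = size
        out = np.zeros((h, w), dtype=bool)
        if len(self.pixels):
            out[self.pixels[:, 1], self.pixels[:, 0]] = True
        return out

    def linear_indices(self, width: int) -> np.ndarray:
        """Sorted unique linear indices v*width + u (for fast set algebra)."""
        return np.sort(self.pixels[:, 1] * width + self.pixels[:, 0])

    def bbox(self) -> tuple[int, int, int, int]:
        """Inclusive bounding box (u_min, v_min, u_max, v_max)."""
        if self.is_empty:
            raise EmptyMaskError("empty mask has no bounding box")
        u, v = self.pixels[:, 0], self.pixels[:, 1]
        return int(u.min()), int(v.min()), int(u.max()), int(v.max())


@dataclass
class DepthImage:
    """Registered metric depth, meters; 0 marks invalid pixels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("depth values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # (H, W)

    def at(self, pixels: np.ndarray) -> np.ndarray:
        """Depth values at an (N, 2) array of (u, v) coordinates."""
        px = np.asarray(pixels)
        return self.values[px[:, 1], px[:, 0]]


@dataclass(frozen=True)
class MaskGeometry:
    """Bounding box, center of mass, and dynamic matching radius of a mask."""

    bbox: tuple[int, int, int, int]  # inclusive (u_min, v_min, u_max, v_max)
    center: tuple[float, float]
    dynamic_radius: float


@dataclass(frozen=True)
class CaliperMeasurement:
    """Manual caliper measurements of one fruit, centimeters."""

    h: float
    w_max: float
    w_min: float

    def __post_init__(self) -> None:
        if self.h < 0 or self.w_min < 0 or self.w_max < 0:
            raise ValueError("caliper measurements must be non-negative")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")


@dataclass(frozen=True)
class DepthWindow:
    """Metric depth acceptance window with an inlier-percentage threshold."""

    tau_l: float
    tau_h: float = float("inf")
    q_threshold: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold <= 100):
            raise ValueError("q_threshold must lie in (0, 100]")
        if np.isfinite(self.tau_h) and self.tau_l >= self.tau_h:
            raise ValueError("tau_l must be below tau_h")


# ---------------------------------------------------------------------------
# per-mask geometry and measurements
# ---------------------------------------------------------------------------

def mask_geometry(mask: InstanceMask, dr_weight: float = 1.0) -> MaskGeometry:
    """Center of mass, bounding box and dynamic radius of a mask.

    The center is the arithmetic mean of the pixel coordinates.  The dynamic
    radius is ``dr_weight`` times the larger of the two inclusive
    bounding-box extents (a 1-pixel object has extent 1).
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot compute geometry of an empty mask")
    if dr_weight <= 0:
        raise ValueError("dr_weight must be positive")
    u_min, v_min, u_max, v_max = mask.bbox()
    extent = max(u_max - u_min + 1, v_max - v_min + 1)
    center = (float(mask.pixels[:, 0].mean()), float(mask.pixels[:, 1].mean()))
    return MaskGeometry(bbox=(u_min, v_min, u_max, v_max), center=center,
                        dynamic_radius=dr_weight * extent)


def estimate_area(mask: InstanceMask, depth: DepthImage,
                  K: CameraIntrinsics) -> tuple[float, int]:
    """Metric surface area of a mask from registered depth, m².

    ``A = Σ_i d_i² / (fx · fy)`` over mask pixels with valid depth; invalid
    pixels contribute nothing.  Returns ``(area, n_valid_pixels)``.
    """
    if mask.is_empty:
        return 0.0, 0
    d = depth.at(mask.pixels)
    valid = d > 0
    area = float(np.sum(d[valid] ** 2) / (K.fx * K.fy))
    return area, int(valid.sum())


def depth_inlier_percentage(mask: InstanceMask, depth: DepthImage,
                            window: DepthWindow) -> float:
    """Percentage of valid-depth mask pixels inside ``[tau_l, tau_h]``.

    Masks with no valid-depth pixel score 0 (treated as outside the window).
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot filter an empty mask")
    d = depth.at(mask.pixels)
    valid = d > 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0
    inliers = (d[valid] >= window.tau_l) & (d[valid] <= window.tau_h)
    return 100.0 * float(inliers.sum()) / n_valid


def fov_filter(masks: list[InstanceMask], image_size: tuple[int, int],
               margin: int = 20, travel_axis: str = "u") -> list[InstanceMask]:
    """Drop masks inside the entry/exit zones or touching any image border.

    A mask survives only if its bounding box lies strictly inside the image
    (no border contact on any side) and outside a ``margin``-wide zone at
    each end of the travel axis.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if travel_axis not in ("u", "v"):
        raise ValueError("travel_axis must be 'u' or 'v'")
    w, h = image_size
    extent = w if travel_axis == "u" else h
    if margin >= extent / 2:
        raise ValueError("margin must be below half the travel-axis extent")
    kept = []
    for m in masks:
        if m.is_empty:
            continue
        u_min, v_min, u_max, v_max = m.bbox()
        if u_min <= 0 or v_min <= 0 or u_max >= w - 1 or v_max >= h - 1:
            continue  # touches (or crosses) a border
        lo, hi = (u_min, u_max) if travel_axis == "u" else (v_min, v_max)
        if lo < margin or hi >= extent - margin:
            continue  # inside an entry/exit zone
        kept.append(m)
    return kept


def caliper_bounds(meas: CaliperMeasurement) -> tuple[float, float]:
    """Rectangular upper bound and trapezoidal lower bound of fruit area, cm².

    ``rec_A = h · w_max`` and ``trp_A = rec_A − h · (w_max − w_min)``.
    """
    rec_a = meas.h * meas.w_max
    trp_a = rec_a - meas.h * (meas.w_max - meas.w_min)
    return rec_a, trp_a


def reproject_instance(mask: InstanceMask, depth: DepthImage,
                       H: FrameTransform, K: CameraIntrinsics) -> InstanceMask:
    """Warp a mask into another frame, carrying its labels unchanged.

    Pixels without valid depth or landing outside the image are dropped; the
    result may be empty (the tracker treats that as unmatched).
    """
    if mask.is_empty:
        pixels = np.empty((0, 2), dtype=np.int64)
    else:
        pixels = reproject_mask(mask.pixels, depth.at(mask.pixels), H, K)
    return InstanceMask(pixels=pixels, super_class=mask.super_class,
                        sub_class=mask.sub_class, confidence=mask.confidence,
                        image_size=(K.width, K.height))


# ---------------------------------------------------------------------------
# annotation I/O (COCO-style JSON dialect)
# ---------------------------------------------------------------------------

def encode_rle(mask: InstanceMask, image_size: tuple[int, int] | None = None) -> dict:
    """Uncompressed column-major run-length encoding (counts start with 0s)."""
    size = image_size or mask.image_size
    if size is None:
        raise ValueError("image_size required for RLE encoding")
    w, h = size
    flat = mask.to_binary(size).flatten(order="F").astype(np.int8)
    # run-length encode, first count is number of leading zeros
    change = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [h, w], "counts": counts}


def decode_rle(rle: dict) -> np.ndarray:
    """Decode an uncompressed column-major RLE into an (N, 2) pixel array."""
    h, w = rle["size"]
    counts = np.asarray(rle["counts"], dtype=np.int64)
    total = int(counts.sum())
    if total != h * w:
        raise ValueError("RLE counts do not cover the image")
    flat = np.zeros(total, dtype=bool)
    pos = np.concatenate([[0], np.cumsum(counts)])
    for k in range(1, len(counts), 2):
        flat[pos[k]:pos[k + 1]] = True
    binary = flat.reshape((h, w), order="F")
    v, u = np.nonzero(binary)
    return np.stack([u, v], axis=1)


def _ring_parity(ring: np.ndarray, uu: np.ndarray, vv: np.ndarray) -> np.ndarray:
    """Even-odd crossing parity of pixel centers w.r.t. one polygon ring."""
    x, y = ring[:, 0], ring[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    inside = np.zeros(uu.shape, dtype=bool)
    for xa, ya, xb, yb in zip(x, y, x2, y2):
        if ya == yb:
            continue
        crosses = (ya > vv) != (yb > vv)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = xa + (vv - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (uu < xint)
    return inside


def rasterize_polygons(polygons: list[list[float]],
                       image_size: tuple[int, int]) -> np.ndarray:
    """Rasterize polygon rings (flat [x0, y0, x1, y1, ...] lists) to pixels.

    Multiple rings (and self-intersections) combine under the even-odd rule;
    pixel centers are the sample points.  Returns an (N, 2) array of (u, v).
    """
    w, h = image_size
    inside = np.zeros((h, w), dtype=bool)
    for flat in polygons:
        ring = np.asarray(flat, dtype=float).reshape(-1, 2)
        if len(ring) < 3:
            continue
        u0 = max(int(np.floor(ring[:, 0].min())), 0)
        u1 = min(int(np.ceil(ring[:, 0].max())) + 1, w)
        v0 = max(int(np.floor(ring[:, 1].min())), 0)
        v1 = min(int(np.ceil(ring[:, 1].max())) + 1, h)
        if u0 >= u1 or v0 >= v1:
            continue
        vv, uu = np.mgrid[v0:v1, u0:u1].astype(float)
        inside[v0:v1, u0:u1] ^= _ring_parity(ring, uu, vv)
    v, u = np.nonzero(inside)
    return np.stack([u, v], axis=1)


def save_annotations(path, frames: dict[int, list[InstanceMask]],
                     image_size: tuple[int, int],
                     super_classes: tuple[str, ...] = ("object",),
                     sub_classes: tuple[str, ...] = ()) -> None:
    """Write per-frame masks to the COCO-style JSON dialect (RLE masks)."""
    w, h = image_size
    images, annotations = [], []
    cat_ids = {name: i + 1 for i, name in enumerate(super_classes)}
    sub_ids = {name: i + 1 for i, name in enumerate(sub_classes)}
    ann_id = 1
    for frame_id in sorted(frames):
        images.append({"id": frame_id, "frame_id": frame_id,
                       "file_name": f"frame_{frame_id:06d}.png",
                       "width": w, "height": h})
        for m in frames[frame_id]:
            annotations.append({
                "id": ann_id,
                "image_id": frame_id,
                "category_id": cat_ids.get(m.super_class, 1),
                "sub_category_id": sub_ids.get(m.sub_class, 0),
                "score": float(m.confidence),
                "segmentation": encode_rle(m, (w, h)),
            })
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": n} for n, i in cat_ids.items()],
        "sub_categories": [{"id": i, "name": n} for n, i in sub_ids.items()],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_annotations(path, sub_class_vocabulary: tuple[str, ...] | None = None
                     ) -> dict[int, list[InstanceMask]]:
    """Load per-frame instance masks from the COCO-style JSON dialect.

    Returns a dict ``frame_id -> [InstanceMask, ...]`` ordered by frame_id.
    Unknown sub-class labels raise :class:`VocabularyError` when a
    vocabulary is supplied.
    """
    with open(path) as fh:
        doc = json.load(fh)
    cat_names = {c["id"]: c["name"] for c in doc.get("categories", [])}
    sub_names = {c["id"]: c["name"] for c in doc.get("sub_categories", [])}
    image_meta = {img["id"]: img for img in doc.get("images", [])}
    frames: dict[int, list[InstanceMask]] = {
        img.get("frame_id", img["id"]): [] for img in doc.get("images", [])
    }
    for ann in doc.get("annotations", []):
        img = image_meta[ann["image_id"]]
        size = (img["width"], img["height"])
        seg = ann["segmentation"]
        if isinstance(seg, dict):
            pixels = decode_rle(seg)
        else:
            if _polygons_self_intersect(seg):
                warnings.warn("self-intersecting polygon decoded by even-odd rule")
            pixels = rasterize_polygons(seg, size)
        sub = sub_names.get(ann.get("sub_category_id"), "")
        if sub_class_vocabulary is not None and sub not in sub_class_vocabulary:
            raise VocabularyError(f"unknown sub-class label: {sub!r}")
        frames.setdefault(img.get("frame_id", img["id"]), []).append(InstanceMask(
            pixels=pixels,
            super_class=cat_names.get(ann.get("category_id"), "object"),
            sub_class=sub,
            confidence=float(ann.get("score", 1.0)),
            image_size=size,
        ))
    return dict(sorted(frames.items()))


def _segments_cross(p, q, r, s) -> bool:
    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
    return (orient(p, q, r) * orient(p, q, s) < 0
            and orient(r, s, p) * orient(r, s, q) < 0)


def _polygons_self_intersect(polygons: list[list[float]]) -> bool:
    for flat in polygons:
        ring = np.asarray(flat, dtype=float).reshape(-1, 2)
        n = len(ring)
        if n < 4:
            continue
        edges = [(ring[i], ring[(i + 1) % n]) for i in range(n)]
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue  # adjacent through the wrap-around
                if _segments_cross(*edges[i], *edges[j]):
                    return True
    return False
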