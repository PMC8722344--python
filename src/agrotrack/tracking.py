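"""Tracking-via-segmentation: greedy association of per-frame masks.

Each physical object accumulates into one :class:`Tracklet` as the platform
traverses a row.  Per frame, candidate detections are filtered (depth
window, field-of-view zones), compared to every active tracklet under the
configured matching criterion, and assigned greedily; unmatched candidates
spawn new tracklets and stale tracklets are closed after ``alpha``
missed frames.

Two matching criteria are supported, each with optional odometry-based
reprojection of the tracklet's last mask into the current frame:

* ``"iou"`` — pixel-set intersection-over-union, gated by ``gamma``;
* ``"dr"``  — dynamic radius: candidate centers within a radius
  proportional to the tracklet's bounding-box extent, nearest center wins.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CameraIntrinsics, RigidPose, relative_camera_transform
from .instances import (
    DepthImage,
    DepthWindow,
    InstanceMask,
    MaskGeometry,
    depth_inlier_percentage,
    estimate_area,
    fov_filter,
    mask_geometry,
    reproject_instance,
)

__all__ = [
    "CameraRig",
    "FrameRecord",
    "TrackerConfig",
    "Tracklet",
    "TrackSet",
    "RowReport",
    "iou_affinity",
    "dr_match",
    "greedy_assign",
    "track_sequence",
    "yield_report",
]


@dataclass(frozen=True)
class CameraRig:
    """Camera intrinsics plus extrinsics mapping camera frame to odometry body."""

    intrinsics: CameraIntrinsics
    extrinsics: RigidPose = field(default_factory=RigidPose.identity)


@dataclass
class FrameRecord:
    """Synchronized data of one timestamp: detections, depth, odometry."""

    frame_id: int
    detections: list[InstanceMask] = field(default_factory=list)
    depth: DepthImage | None = None
    pose: RigidPose | None = None  # world-from-body odometry
    timestamp_s: float = 0.0


@dataclass(frozen=True)
class TrackerConfig:
    """Hyper-parameters of the tracker.

    Defaults follow the operating point used for row monitoring: IoU gate
    0.1, keep-alive of 5 missed frames, 10 matched detections to validate a
    tracklet, and dynamic-radius weight 1.0.  When striding (frame skips)
    the minimum track length is typically reduced (e.g. to 3) because
    objects remain in view for fewer processed frames.
    """

    gamma: float = 0.1
    alpha: int = 5
    min_track_length: int = 10
    criterion: str = "iou"  # "iou" | "dr"
    reprojection: bool = False
    dr_weight: float = 1.0
    depth_window: DepthWindow | None = None
    fov_margin: int = 20
    travel_axis: str = "u"
    frame_stride: int = 1
    subclass_vote: str = "majority"  # "majority" | "last" | "confidence"

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.alpha < 0 or self.min_track_length < 1 or self.frame_stride < 1:
            raise ValueError("alpha >= 0, min_track_length >= 1, frame_stride >= 1")
        if self.dr_weight <= 0:
            raise ValueError("dr_weight must be positive")
        if self.criterion not in ("iou", "dr"):
            raise ValueError("criterion must be 'iou' or 'dr'")
        if self.subclass_vote not in ("majority", "last", "confidence"):
            raise ValueError("unknown subclass_vote mode")


@dataclass
class TrackletEntry:
    frame_id: int
    mask: InstanceMask
    area_m2: float
    sub_class: str
    confidence: float


@dataclass
class Tracklet:
    """Identity of one object across frames."""

    id: int
    history: list[TrackletEntry] = field(default_factory=list)
    frames_since_update: int = 0
    state: str = "active"  # "active" | "closed"
    # frame context of the last matched mask, needed for reprojection
    last_depth: DepthImage | None = None
    last_pose: RigidPose | None = None

    @property
    def last_mask(self) -> InstanceMask:
        return self.history[-1].mask

    @property
    def n_matches(self) -> int:
        return len(self.history)

    def append(self, frame: FrameRecord, mask: InstanceMask,
               area_m2: float) -> None:
        if self.history and frame.frame_id <= self.history[-1].frame_id:
            raise ValueError("frame ids along a tracklet must increase")
        self.history.append(TrackletEntry(frame.frame_id, mask, area_m2,
                                          mask.sub_class, mask.confidence))
        self.frames_since_update = 0
        self.last_depth = frame.depth
        self.last_pose = frame.pose

    def max_area_m2(self) -> float:
        return max((e.area_m2 for e in self.history), default=0.0)

    def vote_sub_class(self, mode: str = "majority") -> str:
        if mode == "last":
            return self.history[-1].sub_class
        if mode == "confidence":
            weights: Counter = Counter()
            for e in self.history:
                weights[e.sub_class] += e.confidence
        else:
            weights = Counter(e.sub_class for e in self.history)
        best = max(weights.values())
        tied = {label for label, w in weights.items() if w == best}
        if len(tied) == 1:
            return tied.pop()
        # tie: most recent frame's label among the tied ones
        for e in reversed(self.history):
            if e.sub_class in tied:
                return e.sub_class
        return self.history[-1].sub_class


@dataclass
class TrackSet:
    """All tracklets produced by one row traverse, plus provenance."""

    tracklets: list[Tracklet]
    config: TrackerConfig
    n_frames_processed: int = 0

    def valid_tracklets(self) -> list[Tracklet]:
        return [t for t in self.tracklets
                if t.n_matches >= self.config.min_track_length]

    def to_json(self, path) -> None:
        doc = {
            "config": {k: (v if not isinstance(v, DepthWindow) else
                           {"tau_l": v.tau_l, "tau_h": v.tau_h,
                            "q_threshold": v.q_threshold})
                       for k, v in self.config.__dict__.items()},
            "n_frames_processed": self.n_frames_processed,
            "tracklets": [
                {
                    "id": t.id,
                    "frames": [e.frame_id for e in t.history],
                    "sub_classes": [e.sub_class for e in t.history],
                    "areas_m2": [e.area_m2 for e in t.history],
                    "confidences": [e.confidence for e in t.history],
                }
                for t in self.tracklets
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


@dataclass
class RowReport:
    """Per-row yield: sub-class counts and per-object maximum areas."""

    counts: dict[str, int]
    total: int
    max_areas_m2: dict[int, float]  # tracklet id -> max area over its history
    sub_class_of: dict[int, str]

    @property
    def max_areas_cm2(self) -> dict[int, float]:
        return {k: v * 1e4 for k, v in self.max_areas_m2.items()}

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total": self.total,
            "max_areas_cm2": self.max_areas_cm2,
            "sub_class_of": dict(self.sub_class_of),
        }


# ---------------------------------------------------------------------------
# matching primitives
# ---------------------------------------------------------------------------

def iou_affinity(a: InstanceMask, b: InstanceMask) -> float:
    """Pixel-set intersection-over-union of two masks (0 if either empty)."""
    if a.is_empty or b.is_empty:
        return 0.0
    # linear index set algebra; width large enough for both masks
    width = int(max(a.pixels[:, 0].max(), b.pixels[:, 0].max())) + 1
    ia = a.linear_indices(width)
    ib = b.linear_indices(width)
    inter = np.intersect1d(ia, ib, assume_unique=True).size
    union = ia.size + ib.size - inter
    return inter / union


def dr_match(tracklet_geom: MaskGeometry,
             candidates: list[MaskGeometry]) -> int | None:
    """Nearest candidate whose center lies within the tracklet's radius.

    Returns the index of the match, or None when no candidate qualifies.
    """
    best_idx, best_dist = None, np.inf
    tc = np.asarray(tracklet_geom.center)
    for idx, geom in enumerate(candidates):
        dist = float(np.linalg.norm(np.asarray(geom.center) - tc))
        if dist <= tracklet_geom.dynamic_radius and dist < best_dist:
            best_idx, best_dist = idx, dist
    return best_idx


def greedy_assign(affinity: np.ndarray, gamma: float
                  ) -> tuple[list[tuple[int, int]], list[int]]:
    """Greedy argmax-and-zero assignment.

    Repeatedly takes the globally maximal entry strictly above ``gamma``,
    records the (row, column) pair, and removes that row and column from
    further consideration, until no entry exceeds the gate.  Ties resolve
    to the lowest row index, then the lowest column index.

    Returns ``(pairs, unmatched_columns)``.
    """
    A = np.array(affinity, dtype=float, copy=True)
    if A.ndim != 2:
        raise ValueError("affinity must be a 2-D matrix")
    pairs: list[tuple[int, int]] = []
    if A.size:
        while True:
            flat = int(np.argmax(A))  # row-major argmax -> lowest row, then col
            i, j = divmod(flat, A.shape[1])
            if not A[i, j] > gamma:
                break
            pairs.append((i, j))
            A[i, :] = -np.inf
            A[:, j] = -np.inf
    matched_cols = {j for _, j in pairs}
    unmatched = [j for j in range(affinity.shape[1]) if j not in matched_cols]
    return pairs, unmatched


# ---------------------------------------------------------------------------
# sequence tracking
# ---------------------------------------------------------------------------

def _reference_masks(active: list[Tracklet], frame: FrameRecord,
                     config: TrackerConfig, rig: CameraRig | None
                     ) -> list[InstanceMask]:
    """Last mask of each active tracklet, reprojected when configured."""
    refs = []
    for t in active:
        mask = t.last_mask
        if config.reprojection:
            H = relative_camera_transform(t.last_pose, frame.pose,
                                          rig.extrinsics)
            mask = reproject_instance(mask, t.last_depth, H, rig.intrinsics)
        refs.append(mask)
    return refs


def track_sequence(frames: list[FrameRecord], config: TrackerConfig,
                   rig: CameraRig | None = None) -> TrackSet:
    """Run the tracker over an ordered sequence of frame records.

    ``frames`` must carry detections (from a file-backed or synthetic
    detector).  ``rig`` is required when reprojection or area estimation is
    wanted.  ``config.frame_stride`` subsamples the sequence before any
    processing; ``alpha`` counts processed (post-stride) frames.
    """
    if config.reprojection:
        if rig is None:
            raise ValueError("reprojection requires a camera rig")
        if any(f.pose is None or f.depth is None for f in frames):
            raise ValueError("reprojection requires odometry and depth "
                             "for every frame")
    if config.depth_window is not None and any(f.depth is None for f in frames):
        raise ValueError("depth filtering requires depth for every frame")

    processed = frames[::config.frame_stride]
    tracklets: list[Tracklet] = []
    next_id = 0

    for frame in processed:
        masks = list(frame.detections)
        if config.depth_window is not None:
            masks = [m for m in masks if not m.is_empty and
                     depth_inlier_percentage(m, frame.depth, config.depth_window)
                     > config.depth_window.q_threshold]
        if rig is not None:
            size = (rig.intrinsics.width, rig.intrinsics.height)
        elif masks and masks[0].image_size is not None:
            size = masks[0].image_size
        else:
            size = None
        if size is not None:
            masks = fov_filter(masks, size, margin=config.fov_margin,
                               travel_axis=config.travel_axis)
        masks = [m for m in masks if not m.is_empty]

        active = [t for t in tracklets if t.state == "active"]
        pairs: list[tuple[int, int]] = []
        unmatched = list(range(len(masks)))
        if active and masks:
            refs = _reference_masks(active, frame, config, rig)
            if config.criterion == "iou":
                A = np.array([[iou_affinity(r, m) for m in masks]
                              for r in refs])
                pairs, unmatched = greedy_assign(A, config.gamma)
            else:  # dynamic radius: affinity = -distance gated by radius
                cand_geoms = [mask_geometry(m, config.dr_weight) for m in masks]
                A = np.full((len(refs), len(masks)), -np.inf)
                for i, r in enumerate(refs):
                    if r.is_empty:
                        continue
                    g = mask_geometry(r, config.dr_weight)
                    tc = np.asarray(g.center)
                    for j, cg in enumerate(cand_geoms):
                        d = float(np.linalg.norm(np.asarray(cg.center) - tc))
                        if d <= g.dynamic_radius:
                            A[i, j] = -d
                pairs, unmatched = greedy_assign(A, -np.inf)

        matched_tracklets = set()
        for i, j in pairs:
            t = active[i]
            area = 0.0
            if frame.depth is not None and rig is not None:
                area, _ = estimate_area(masks[j], frame.depth, rig.intrinsics)
            t.append(frame, masks[j], area)
            matched_tracklets.add(t.id)

        for j in unmatched:
            area = 0.0
            if frame.depth is not None and rig is not None:
                area, _ = estimate_area(masks[j], frame.depth, rig.intrinsics)
            t = Tracklet(id=next_id)
            next_id += 1
            t.append(frame, masks[j], area)
            tracklets.append(t)

        # Ψ: retire tracklets idle for more than alpha processed frames
        for t in tracklets:
            if t.state == "active" and t.id not in matched_tracklets \
                    and t.history and t.history[-1].frame_id != frame.frame_id:
                t.frames_since_update += 1
                if t.frames_since_update > config.alpha:
                    t.state = "closed"

    for t in tracklets:
        t.state = "closed"
    return TrackSet(tracklets=tracklets, config=config,
                    n_frames_processed=len(processed))


def yield_report(tracks: TrackSet, config: TrackerConfig | None = None
                 ) -> RowReport:
    """Aggregate a track set into per-row yield counts and maximum areas.

    Tracklets shorter than ``min_track_length`` are dropped; each surviving
    tracklet contributes one count to its voted sub-class and reports the
    maximum of its per-frame areas.
    """
    cfg = config or tracks.config
    counts: Counter = Counter()
    max_areas: dict[int, float] = {}
    sub_of: dict[int, str] = {}
    for t in tracks.tracklets:
        if t.n_matches < cfg.min_track_length:
            continue
        label = t.vote_sub_class(cfg.subclass_vote)
        counts[label] += 1
        max_areas[t.id] = t.max_area_m2()
        sub_of[t.id] = label
    return RowReport(counts=dict(counts), total=sum(counts.values()),
                     max_areas_m2=max_areas, sub_class_of=sub_of)
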