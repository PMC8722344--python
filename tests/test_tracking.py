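import itertools

import numpy as np
import pytest

from agrotrack.instances import DepthWindow, InstanceMask, mask_geometry
from agrotrack.tracking import (
    FrameRecord,
    RowReport,
    TrackerConfig,
    Tracklet,
    TrackSet,
    dr_match,
    greedy_assign,
    iou_affinity,
    track_sequence,
    yield_report,
)
from conftest import square_mask


def greedy_oracle(matrix, gamma):
    """Brute-force argmax-and-zero re-implementation (pure python)."""
    m = [row[:] for row in matrix]
    rows, cols = len(m), len(m[0]) if m else 0
    pairs = []
    used_r, used_c = set(), set()
    while True:
        best = gamma
        best_ij = None
        for i in range(rows):
            if i in used_r:
                continue
            for j in range(cols):
                if j in used_c:
                    continue
                if m[i][j] > best:
                    best = m[i][j]
                    best_ij = (i, j)
        if best_ij is None:
            return pairs
        pairs.append(best_ij)
        used_r.add(best_ij[0])
        used_c.add(best_ij[1])


class TestIoUAffinity:
    def test_identical_masks(self):
        m = square_mask(5, 5, 10)
        assert iou_affinity(m, m) == 1.0

    def test_disjoint_masks(self):
        assert iou_affinity(square_mask(0, 0, 5), square_mask(50, 50, 5)) == 0.0

    def test_offset_squares(self):
        # 10x10 squares offset by (5, 5): overlap 25, union 175
        a = square_mask(0, 0, 10)
        b = square_mask(5, 5, 10)
        assert iou_affinity(a, b) == pytest.approx(25 / 175)

    def test_empty_mask_zero(self):
        empty = InstanceMask(pixels=np.empty((0, 2)))
        assert iou_affinity(empty, square_mask(0, 0, 3)) == 0.0

    def test_small_object_large_shift(self):
        # the fragmentation mechanism: 10x10 square shifted 9 px
        a = square_mask(0, 0, 10)
        b = square_mask(9, 0, 10)
        assert iou_affinity(a, b) == pytest.approx(10 / 190)
        assert iou_affinity(a, b) < 0.1


class TestDrMatch:
    def test_within_radius_matched(self):
        t = mask_geometry(square_mask(0, 0, 10))  # center (4.5,4.5), radius 10
        c = mask_geometry(square_mask(9, 0, 10))  # center (13.5,4.5), dist 9
        assert dr_match(t, [c]) == 0

    def test_candidate_at_center(self):
        t = mask_geometry(square_mask(0, 0, 10))
        c = mask_geometry(square_mask(0, 0, 10))
        assert dr_match(t, [c]) == 0

    def test_all_outside_radius(self):
        t = mask_geometry(square_mask(0, 0, 10))
        far = mask_geometry(square_mask(100, 100, 10))
        assert dr_match(t, [far]) is None

    def test_nearest_wins(self):
        t = mask_geometry(square_mask(0, 0, 10))
        near = mask_geometry(square_mask(2, 0, 10))
        nearer = mask_geometry(square_mask(1, 0, 10))
        assert dr_match(t, [near, nearer]) == 1


class TestGreedyAssign:
    def test_single_entry(self):
        pairs, unmatched = greedy_assign(np.array([[0.5]]), 0.1)
        assert pairs == [(0, 0)] and unmatched == []

    def test_two_by_two_derived(self):
        A = np.array([[0.9, 0.8], [0.85, 0.2]])
        pairs, unmatched = greedy_assign(A, 0.1)
        assert pairs == [(0, 0), (1, 1)]
        assert unmatched == []
        assert pairs == greedy_oracle(A.tolist(), 0.1)

    def test_all_below_gamma(self):
        pairs, unmatched = greedy_assign(np.full((2, 3), 0.05), 0.1)
        assert pairs == [] and unmatched == [0, 1, 2]

    def test_one_to_one(self, rng):
        for _ in range(50):
            A = rng.random((4, 5))
            pairs, unmatched = greedy_assign(A, 0.3)
            rows = [i for i, _ in pairs]
            cols = [j for _, j in pairs]
            assert len(rows) == len(set(rows))
            assert len(cols) == len(set(cols))
            assert sorted(cols + unmatched) == list(range(5))

    def test_matches_oracle_random(self, rng):
        for _ in range(200):
            shape = rng.integers(1, 5, size=2)
            A = np.round(rng.random(shape) / 0.05) * 0.05
            assert greedy_assign(A, 0.1)[0] == greedy_oracle(A.tolist(), 0.1)

    def test_tie_break_lowest_row_then_col(self):
        A = np.array([[0.5, 0.5], [0.5, 0.5]])
        pairs, _ = greedy_assign(A, 0.1)
        assert pairs == [(0, 0), (1, 1)]


def static_frames(n_frames, squares):
    """Frames with the same detections each frame (static camera)."""
    frames = []
    for f in range(n_frames):
        dets = [square_mask(u, v, s, sub_class=c, image_size=(200, 200))
                for (u, v, s, c) in squares]
        frames.append(FrameRecord(frame_id=f, detections=dets))
    return frames


class TestTrackSequence:
    def test_static_objects_one_tracklet_each(self):
        squares = [(20 + 30 * i, 50, 10, "Gn") for i in range(5)]
        frames = static_frames(50, squares)
        for criterion in ("iou", "dr"):
            cfg = TrackerConfig(criterion=criterion, min_track_length=10,
                                fov_margin=5)
            tracks = track_sequence(frames, cfg)
            report = yield_report(tracks)
            assert report.total == 5
            assert len(tracks.tracklets) == 5

    def test_empty_stream(self):
        cfg = TrackerConfig()
        tracks = track_sequence([FrameRecord(frame_id=f) for f in range(5)],
                                cfg)
        assert tracks.tracklets == []
        assert yield_report(tracks).total == 0

    def test_translating_small_object_fragments_iou_not_dr(self):
        # 10 px object moving 9 px/frame: per-frame IoU 10/190 < 0.1
        frames = [FrameRecord(frame_id=f, detections=[
            square_mask(10 + 9 * f, 50, 10, image_size=(200, 200))])
            for f in range(15)]
        iou_tracks = track_sequence(
            frames, TrackerConfig(criterion="iou", gamma=0.1,
                                  min_track_length=1, fov_margin=4, alpha=0))
        dr_tracks = track_sequence(
            frames, TrackerConfig(criterion="dr", min_track_length=1,
                                  fov_margin=4, alpha=0))
        assert len(iou_tracks.tracklets) > 1
        assert len(dr_tracks.tracklets) == 1

    def test_alpha_keep_alive(self):
        # object missing for 2 frames; alpha=2 bridges it, alpha=1 does not
        frames = []
        for f in range(12):
            dets = ([] if f in (5, 6) else
                    [square_mask(50, 50, 10, image_size=(200, 200))])
            frames.append(FrameRecord(frame_id=f, detections=dets))
        bridged = track_sequence(frames, TrackerConfig(
            alpha=2, min_track_length=1, fov_margin=5))
        split = track_sequence(frames, TrackerConfig(
            alpha=1, min_track_length=1, fov_margin=5))
        assert len(bridged.tracklets) == 1
        assert len(split.tracklets) == 2

    def test_conservation_every_detection_assigned(self):
        squares = [(30, 30, 10, "a"), (80, 80, 12, "b"), (140, 60, 8, "c")]
        frames = static_frames(20, squares)
        tracks = track_sequence(frames, TrackerConfig(min_track_length=1,
                                                      fov_margin=5))
        n_assigned = sum(t.n_matches for t in tracks.tracklets)
        assert n_assigned == 20 * 3

    def test_determinism(self):
        squares = [(30, 30, 10, "a"), (45, 30, 10, "b"), (80, 80, 12, "c")]
        frames = static_frames(25, squares)
        cfg = TrackerConfig(min_track_length=5, fov_margin=5)
        a = track_sequence(frames, cfg)
        b = track_sequence(static_frames(25, squares), cfg)
        assert [(t.id, [e.frame_id for e in t.history]) for t in a.tracklets] \
            == [(t.id, [e.frame_id for e in t.history]) for t in b.tracklets]

    def test_frame_stride_subsamples(self):
        squares = [(50, 50, 20, "a")]
        frames = static_frames(50, squares)
        cfg = TrackerConfig(min_track_length=3, frame_stride=5, fov_margin=5)
        tracks = track_sequence(frames, cfg)
        assert tracks.n_frames_processed == 10
        assert tracks.tracklets[0].n_matches == 10

    def test_reprojection_requires_rig_and_odometry(self):
        frames = static_frames(5, [(50, 50, 10, "a")])
        cfg = TrackerConfig(reprojection=True)
        with pytest.raises(ValueError):
            track_sequence(frames, cfg)

    def test_depth_filter_requires_depth(self):
        frames = static_frames(5, [(50, 50, 10, "a")])
        cfg = TrackerConfig(depth_window=DepthWindow(0.4, 1.0))
        with pytest.raises(ValueError):
            track_sequence(frames, cfg)


def tracklet_with_labels(labels, tid=0):
    t = Tracklet(id=tid)
    for f, label in enumerate(labels):
        t.append(FrameRecord(frame_id=f),
                 square_mask(0, 0, 4, sub_class=label), 0.0)
    return t


class TestYieldReport:
    def make_set(self, tracklets, **cfg):
        config = TrackerConfig(**cfg)
        return TrackSet(tracklets=tracklets, config=config)

    def test_min_track_length_boundary(self):
        short = tracklet_with_labels(["Gn"] * 9)
        tracks = self.make_set([short], min_track_length=10)
        assert yield_report(tracks).total == 0

    def test_majority_vote(self):
        t = tracklet_with_labels(["Gn"] * 12 + ["My"] * 3)
        tracks = self.make_set([t], min_track_length=10)
        report = yield_report(tracks)
        assert report.counts == {"Gn": 1}

    def test_tie_goes_to_most_recent(self):
        t = tracklet_with_labels(["Gn", "My", "Gn", "My"])
        tracks = self.make_set([t], min_track_length=1)
        assert yield_report(tracks).counts == {"My": 1}

    def test_max_area_reported(self):
        t = Tracklet(id=0)
        for f, area in enumerate([30e-4, 44e-4, 38e-4]):
            t.append(FrameRecord(frame_id=f), square_mask(0, 0, 4), area)
        tracks = self.make_set([t], min_track_length=1)
        report = yield_report(tracks)
        assert report.max_areas_cm2[0] == pytest.approx(44.0)

    def test_total_is_sum_of_counts(self):
        ts = [tracklet_with_labels(["Gn"] * 4, 0),
              tracklet_with_labels(["Rd"] * 4, 1),
              tracklet_with_labels(["Gn"] * 4, 2)]
        report = yield_report(self.make_set(ts, min_track_length=2))
        assert report.total == sum(report.counts.values()) == 3

    def test_last_vote_mode(self):
        t = tracklet_with_labels(["Gn"] * 5 + ["Rd"])
        tracks = self.make_set([t], min_track_length=1, subclass_vote="last")
        assert yield_report(tracks).counts == {"Rd": 1}


class TestTrackletInvariants:
    def test_frame_ids_strictly_increase(self):
        t = tracklet_with_labels(["a", "b"])
        with pytest.raises(ValueError):
            t.append(FrameRecord(frame_id=0), square_mask(0, 0, 2), 0.0)

    def test_serialization(self, tmp_path):
        t = tracklet_with_labels(["Gn", "Gn"])
        ts = TrackSet(tracklets=[t], config=TrackerConfig())
        path = tmp_path / "tracks.json"
        ts.to_json(path)
        import json
        doc = json.loads(path.read_text())
        assert doc["tracklets"][0]["frames"] == [0, 1]
        assert doc["tracklets"][0]["sub_classes"] == ["Gn", "Gn"]
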