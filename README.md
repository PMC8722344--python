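# agrotrack

Platform-agnostic crop-row monitoring from per-frame instance segmentation.
Given per-frame instance masks (with coarse super-class and fine-grained
sub-class labels), registered metric depth, camera calibration, and wheel
odometry, `agrotrack`:

- tracks each plant/fruit across a row traverse (tracking-via-segmentation
  with greedy assignment under an **IoU** or **dynamic-radius** matching
  criterion, each with optional odometry-based **mask reprojection**),
- filters detections by a metric depth window so only the current row is
  counted,
- estimates per-object surface area from depth (`A = Σ dᵢ² / (fx·fy)`),
- reports per-row, per-sub-class yield counts and maximum areas,
- evaluates with detection PR/F1, instance/semantic segmentation IoU,
  confusion accuracy, mean normalized absolute error (μNAE) and R²,
- and ships a synthetic row-traverse simulator (ground-plane "field" scenes
  and crop-wall "wall" scenes with a distractor depth layer, plus detector
  corruption models) so the whole pipeline is testable end to end without
  any recorded data.

## CLI

The `agrotrack` command chains the pipeline: simulate → track → evaluate →
report. Every run directory gets a provenance block (config hash, seed,
version).

```bash
# render a synthetic field row to ./data (masks, 16-bit depth PNGs,
# odometry JSONL, intrinsics YAML, ground-truth manifest CSV)
agrotrack simulate --mode field --n-objects 20 --speed 0.01 \
    --row-length 3.0 --seed 1 --out data

# track it with dynamic radius + reprojection, sweeping depth windows
agrotrack track --data data --criterion dr --reproject \
    --tau-h 1.0 --tau-h 1.4 --tau-h none --out run

# score predicted counts against visual ground truth
agrotrack evaluate --gt data/manifest.csv --pred run/pred_counts.csv

# human-readable summary of a run
agrotrack report --run run
```

Tracker defaults: IoU gate `gamma = 0.1`, keep-alive `alpha = 5` missed
frames, 10 matched detections to validate a tracklet, dynamic-radius
weight 1.0, depth inlier threshold `q > 50 %`. With `--frame-stride 5`
(large frame skips) reduce `--min-track-length` to 3.

## Library layout

| module                | contents                                                        |
|-----------------------|-----------------------------------------------------------------|
| `agrotrack.geometry`  | pinhole project/backproject, rigid poses, odometry-conjugated frame transforms, mask reprojection |
| `agrotrack.instances` | `InstanceMask` model, COCO-style annotation I/O, mask geometry (center of mass, dynamic radius), depth-based area, depth-window inlier %, FOV entry/exit filtering, caliper area bounds |
| `agrotrack.tracking`  | greedy assignment, IoU/DR affinities, tracklet lifecycle, `track_sequence`, yield reports |
| `agrotrack.metrics`   | detection matching, F1/PR curves, instance-vs-semantic segmentation protocols, confusion accuracy, μNAE, R², row-count CSV I/O |
| `agrotrack.synthetic` | scene generation, traverse rendering, detector corruption |
| `agrotrack.io`        | dataset directory read/write (YAML intrinsics, JSONL odometry, 16-bit depth PNG, annotation JSON) |
| `agrotrack.cli`       | `agrotrack` command group |

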