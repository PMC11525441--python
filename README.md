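# kinemotion

Kinematic feature extraction for full-body motion-capture recordings and
silhouette videos, plus a synthetic emotion-modulated choreography
generator so the whole pipeline can be exercised without any proprietary
hardware or dataset.

The package computes 12 kinematic features, summarized into 32
(feature, statistic) kinds per sequence:

| Feature | Source | Statistics |
| --- | --- | --- |
| speed, acceleration, angular speed, angular acceleration | keypoint series | average, MAD, max (per keypoint + all-joint mean) |
| limb contraction, distance to center of mass | keypoint series | average, MAD |
| head tilt w.r.t. back / w.r.t. vertical | keypoint series | average, MAD |
| quantity of motion (QoM) | silhouette masks | average, MAD, integral |
| dimensionless jerk | keypoint series | one scalar (integral) |
| convex hull 3D / 2D | keypoint series / CamPos | average, MAD, global, union |

MAD is the median of absolute deviations from the series median (no
consistency constant). Derivatives use central finite differences with
second-order one-sided boundaries; Euler orientation channels are
unwrapped per axis before differentiation.

## Modules

- `kinemotion.motion_io` — MVNX-style XML parsing, per-quantity CSV
  read/write, pinhole CamPos projection (screen-ratio x/y + metric
  depth, JSON), framerate resampling.
- `kinemotion.kinematics` — the 12 features, aggregation, and the
  long-format summary table (`extract_all`).
- `kinemotion.silhouette` — boolean-mask clips: silhouette motion mask,
  QoM, foreground statistics, PNG sequence I/O.
- `kinemotion.synthetic` — emotion-modulated choreography generator
  (constant bone lengths, per-emotion speed / expansion / smoothness /
  head-tilt / pause modulation), capsule silhouette renderer, MVNX
  writer, and the 9-sequence x (6 emotions + 1 explanation take)
  dataset builder (54 emotional / 63 total entries).
- `kinemotion.ratings` — forced-choice observer analysis: confusion
  matrices, recognition summaries, chance-level chi-square tests.
- `kinemotion.cli` — the `kinemotion` command.

## Command line

```sh
# build a synthetic dataset (MVNX + CSV + CamPos + silhouette masks + manifest)
kinemotion synth --out scratch/dataset --seed 7 --sequences 9 --duration 6

# convert an MVNX-style recording
kinemotion convert --mvnx recording.mvnx --out out/ --csv --campos --hz 60

# extract the 32 summary statistics for one sequence
kinemotion extract --in recording.mvnx --campos campos.json \
    --silhouette masks/ --out out/ --voxel 0.01

# quantity of motion from a PNG mask sequence
kinemotion qom --frames masks/ --delta 5 --fps 25 --out qom.csv

# observer-rating analysis
kinemotion ratings --in ratings.csv --by presentation --out out/

# synthetic build -> extraction -> invariant round trip
kinemotion validate --out scratch/validate --seed 1
```

## Notes

- QoM's history span delta is not standardized; the default is 5 frames
  and every output records the value used.
- The 3D hull union is approximated on a voxel grid (default 1 cm,
  `--voxel`) and clipped to the global hull volume; the 2D union is an
  exact polygon union.
- The dimensionless jerk defaults to the center-of-mass trajectory
  (`--jerk-trajectory` to use a keypoint instead).
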