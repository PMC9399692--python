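# myovol

Headless reconstruction of three-dimensional muscle volumes from bone
surface meshes and "painted" attachment areas.

Given a triangle mesh of a bone and two face-index selections (the muscle's
origin and insertion attachment areas), `myovol`:

1. measures the attachment areas and their area-weighted centroids;
2. spans a centerline curve between the centroids (interior control points
   can be displaced to model muscle curvature);
3. projects the origin boundary to its best-fit plane and sweeps that
   cross-section along the centerline in rotation-minimizing frames,
   blending toward the insertion boundary, producing a watertight muscle
   mesh built from selectable cross-section rings;
4. removes muscle–bone and muscle–muscle overlap by Boolean difference with
   a deterministic priority order;
5. exports per-muscle metrics (areas, centroids, linear and curved lengths,
   enclosed volume) together with truncated-cone ("frustum") volume, PCSA
   and isometric-force comparison statistics.

Everything is plain scientific Python (numpy, scipy, shapely, click); mesh
I/O supports OBJ, ASCII PLY and ASCII STL. The Boolean engine is an
in-package plane-based BSP solid-modelling kernel with welding, T-junction
stitching and tangential-contact handling.

PCSA is computed as volume / length under the parallel-fibred assumption
(fibre length = muscle length); forces use an isometric muscle stress of
0.3 N/mm² by default. These outputs are comparative quantities, not
absolute force predictions.

## CLI

Generate a synthetic test scene, run the pipeline on it, and inspect the
metrics:

```sh
myovol fixtures generate --name parallel-plates --out scene/
myovol generate --config scene/config.json --out results/
cat results/metrics.csv
```

`generate` reads a single JSON config (bone mesh paths, selection sidecars,
per-muscle centerline offsets, sweep parameters, Boolean priority, stress,
seed) and writes one OBJ per muscle, `metrics.csv`, `manifest.json`,
`overlaps.json` and a machine-parseable `run.log`.

Attachment selections are JSON sidecars:

```json
{"mesh": "bone", "muscle": "mAMEP", "role": "origin", "faces": [12, 13, 14]}
```

Face indices are 0-based.

The numeric comparison layer is exposed standalone: given a CSV with columns
`name,A_or,A_ins,linear_length,muscle_length,volume_3d`, emit frustum
volumes, both PCSAs, both forces and all percent-difference columns:

```sh
myovol frustum measurements.csv --out comparison.csv
```

Available fixtures: `parallel-plates` (straight cylindrical muscle with
analytic volume), `curved-channel` (quarter-circle muscle exercising
curved- vs linear-length divergence, volume via Pappus), and
`overlap-pair` (two intersecting muscles with a closed-form lens
intersection volume).

## Layout

- `src/myovol/mesh_core.py` — triangle-mesh geometry: areas, centroids,
  enclosed volume, boundary loops, watertightness, PCA plane alignment
- `src/myovol/centerline.py` — centerline curves (clamped Catmull-Rom),
  linear and curved lengths
- `src/myovol/sweep.py` — boundary resampling, rotation-minimizing frames,
  the sweep itself, per-ring scaling
- `src/myovol/boolean_ops.py` — BSP Boolean kernel and overlap resolution
- `src/myovol/metrics.py` — frustum/PCSA/force statistics and the CSV layer
- `src/myovol/fixtures.py` — deterministic synthetic scenes with analytic
  expectations
- `src/myovol/io.py`, `src/myovol/primitives.py`, `src/myovol/cli.py`
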