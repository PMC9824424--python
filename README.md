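# cabbagemorph

Non-destructive phenotyping of cabbage (*Brassica oleracea*) from top-down
imagery: given per-instance segmentation masks (whole plant, head, single
leaves) and a co-registered depth raster, the package estimates the hidden
3D leaf-attachment point, per-leaf 3D lengths, total leaf area by a
length-based allometry, and head volume under a sphere model. It is written
for crop-monitoring researchers who already have instance masks (e.g. from a
Mask R-CNN) and photogrammetric depth maps and want per-plant morphometry
without harvesting.

## Method

For each plant, with leaves assigned by the >80 % mask-overlap rule:

1. **Leaf planes.** Each leaf's mask is back-projected through the depth
   raster into a 3D point cloud (pinhole model, nadir camera). An MSAC
   consensus — RANSAC scored by truncated squared orthogonal residuals
   Σ min(r², tol²) — strips depth outliers, and a multiple linear regression
   z = a·x + b·y + c fits the leaf plane to the inliers.
2. **Attachment point p.** Cabbage leaves converge at the stem, so the leaf
   planes nearly share a point. Every well-conditioned plane triple is solved
   as a 3×3 linear system; intersections that project into the plant mask and
   lie at plausible heights are averaged into p.
3. **Leaf length and area.** The leaf endpoint q is the cloud point farthest
   from p; the length is L = ‖q − p‖. With L̄ the plant's mean leaf length,
   each leaf's area is `L̄ · Lᵢ · 2.7` (the factor absorbs the unobservable
   leaf width), so the total leaf area satisfies `LA = 2.7 · n · L̄²`.
4. **Head volume.** The head mask's pixel count gives an equivalent-circle
   radius r_px = √(area/π); with apex depth Z₀ (robust minimum of in-mask
   depths) the metric radius solves the coupled apex/equator system in closed
   form, r_mm = r_px·Z₀/(f − r_px), and V = 4/3·π·r³.

Segmentation quality is scored with COCO-style mask mAP (greedy matching,
101-point interpolated AP, IoU thresholds 0.50–0.95), and measurement
columns with mean/population-SD/mean-accuracy summaries.

A parametric scene generator (`synthetic_cabbage`) renders funnel plants with
planar elliptical leaves and partially occluded spherical heads — with exact
ground truth — so every stage is testable for parameter recovery without
field data.

## Worked example

```sh
python examples/01_measure_synthetic_plant.py
```

```
attachment point estimate : [ 3.100e-01 -1.000e-02  8.017e+01] mm
  true point              : [ 0.  0. 80.] mm (0.35 mm off)
  from 220 plane-triple intersections, RMS spread 1.5 mm
mean leaf length L̄        : 256.2 mm
total leaf area (2.7·n·L̄²): 2.127 m²
head volume               : 0.00314 m³ (true 0.00305 m³)
```

A 12-leaf synthetic plant with 5 % depth outliers and 2 mm depth noise: the
hidden stem point is recovered to 0.35 mm, and the sphere-model head volume
lands within 3 % of the generator's truth. The other examples cover head
volume under leaf occlusion (`02`), mask mAP on a toy detector (`03`) and the
bundled field-trial tables (`04`).

The same operations are available from a thin CLI:

```sh
cabbage-morph simulate --plants 1 --head-radius 90 --seed 1 --out scene/
cabbage-morph measure-scene --leaf-labels scene/labels_leaf.png \
    --plant-labels scene/labels_plant.png --head-labels scene/labels_head.png \
    --depth scene/depth.png --camera camera.json --seed 1 --out results/
cabbage-morph reproduce-tables
```

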