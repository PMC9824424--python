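# Methods

This note records the measurement model, the conventions and tunables, what
the synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Coordinate and depth conventions

Images are 0-based with origin top-left, addressed as (col, row). The world
frame puts z = 0 on the ground plane with z up, x along +col and y along
+row. Depth rasters store the camera-to-surface distance in millimetres
along the optical axis — what SfM/MVS photogrammetry pipelines produce — so
surface height is `camera_height − depth`. In integer depth rasters a stored
0 is the no-data sentinel. Back-projection is perspective (pinhole) by
default; an orthographic mode exists for analytically simple test scenes.

The default camera is a nadir view from 900 mm, a typical boom height for
row-crop canopy imaging, with a 1000 px focal length (≈ 0.9 mm ground
sampling). Real GoPro-class intrinsics vary; they are always supplied
explicitly, never calibrated from imagery.

## Robust leaf-plane estimation

A segmented cabbage leaf is treated as planar; its depth pixels carry
speckle plus gross outliers (matching failures, pixels bleeding in from an
overlapping leaf). Two steps:

* **MSAC** draws 3-point samples (default 500 iterations, explicit seed),
  scores each candidate plane by Σ min(orthogonal residual², tol²) and keeps
  the minimum-score plane's inliers. The truncation tolerance defaults to
  10 mm — on the order of leaf thickness plus depth noise; it is the single
  most influential tunable and is exposed as `msac.distance_tolerance`.
  Scoring uses orthogonal distances (the usual consensus convention).
* **Refit** by multiple linear regression of z on (x, y) over the inliers
  (vertical residuals). The consensus-then-refit split matters: the 3-point
  sample plane is noisy, the regression plane is not.

An inlier fraction below `min_inlier_fraction` (default 0.5) flags the leaf
`low_support` rather than failing it: in field batches a partially corrupted
leaf should degrade, not abort, the plant record.

## Attachment-point estimation

All leaves of a plant converge at the stem, which the camera cannot see.
"Intersections" of the leaf planes are read as *triple*-plane intersection
points: three planes in general position meet in a point, while plane pairs
meet in lines and admit no canonical point. For every unordered triple the
3×3 system is solved; a triple is discarded when

* the determinant of the row-normalised system matrix is below 1e-6
  (near-parallel planes produce wild far-away points; the threshold is
  scale-free because rows are normalised first),
* the point projects outside the segmented plant area, or
* its height leaves [0, camera_height] — below-ground or above-camera
  points are artefacts.

Surviving points are averaged (arithmetic mean; a median option exists for
robustness experiments but is not the default, since the mean is the
definition of the estimate). The result carries `support` (points averaged)
and `dispersion` (RMS spread), the two quality diagnostics worth logging.
One shared attachment point serves all leaves of a plant: per-leaf variants
were tried in the original field study and found unstable, because central
leaves cap the head spherically and their planes cut far too high.

## Leaf length and allometric area

The endpoint q is the cloud point farthest from p in 3D (ties to first in
scan order); L = ‖q − p‖ deliberately ignores leaf curvature. Areas use the
length-only allometry

    areaᵢ = L̄ · Lᵢ · 2.7  (mm² → m²),   total = Σᵢ areaᵢ = 2.7 · n · L̄²,

where L̄ is the plant's mean leaf length and 2.7 is the cabbage shape factor
standing in for the unobservable width. Only visible leaves enter the totals
— no hidden-leaf correction is applied, matching the reference results. The
published formula typesets this as `LA = 1/n·Σ L·Lᵢ·2.7`; the accompanying
prose ("the individual leaf length is multiplied by the mean value of all
leaf lengths … and a correction factor") is unambiguous and is what is
implemented; the `1/n Σ` produces L̄.

Leaves attach to the plant owning more than 80 % of their mask area
(`assign.threshold`); with several qualifying plants the largest fraction
wins, ties to the lower plant id (the tie rule is an artifact choice — the
source is silent). Unassigned leaves are excluded from all plant totals and
reported separately.

## Head volume

The head mask's pixel count *is* the cross-section estimate:
r_px = √(area/π). An outline or sphere fit was deliberately rejected —
partial leaf cover makes outline fits fragile, and sphere-RANSAC on the
depth cloud is known to latch onto wrong points for this crop. The apex
distance Z₀ is the 5th percentile of in-mask depths (not the minimum, which
a single speckle pixel can corrupt; `head.apex_percentile`). The equator
sits one metric radius past the apex, giving the closed form

    r_mm = r_px · Z₀ / (f − r_px),   H = Z₀ + r_mm,   V = 4/3·π·r_mm³.

The printed source conversion divides by the distance (`r_mm = r_px·k/H`),
which contradicts perspective geometry — farther objects cover more mm per
pixel, not fewer. The default is therefore the pinhole reading
r_mm = r_px·H/f (k ≡ 1/f); the literal form stays selectable
(`eq5_mode="literal"`) so the discrepancy is auditable rather than silently
resolved.

Two intrinsic biases are worth knowing. First, the perspective silhouette
of a sphere is slightly wider than its equatorial cross-section, so the
closed form overestimates volume by O((r_px/f)²): ≈ 2–3 % at the mature-head
scale (r ≈ 90 mm seen from ≈ 700 mm) and ≈ 5–6 % at r = 120 mm. Second, the
conversion assumes near-nadir viewing; a head 600 mm off-axis at f = 750 px
(≈ 39° field angle) foreshortens and under-measures volume by ≈ 20 %. In
row-wise capture each plant is measured near the image centre, where the
first effect dominates and stays within a few percent.

The circumference helper (`volume_from_circumference`) implements the
tape-measure ground truth under the same sphere assumption, and
`reference_scale` converts scanned leaf masks to metric area via a
known-size reference object (two markers disagreeing by > 1 % raise an
inconsistency flag).

## Evaluation statistics

Mask mAP follows the COCO dialect: detections ranked by score, greedy
matching to the unmatched truth of highest IoU ≥ threshold, AP as the mean
of the interpolated precision envelope over a 101-point recall grid, mAP the
mean over thresholds 0.50:0.05:0.95. The source does not state an
integration rule; the COCO convention is the natural one given its
transfer-learning context.

Measurement summaries use the bundled tables' own conventions: population
(divisor-n) standard deviation — which reproduces the tables' printed SD
where the sample SD does not — SD as percent of mean, and mean accuracy
`mean(100·(1 − |est−ref|/ref))` floored at zero per item. Accuracies follow
the tables' reference chain: calculated (method on ground-truth masks) is
judged against hand measurements; detected (method on network masks) is
judged against calculated, its ceiling. The exact accuracy formula of the
source is undocumented; on the bundled mature-stage volume table this
formula yields 86.6 % against a printed 87.2 %, consistent with the summary
having been computed from unrounded data. Similarly, three summary cells of
the mature-stage leaf-area table (and one of the early-stage table)
disagree with their own printed per-plant columns at the last digit; the
package always recomputes summaries from the per-plant values and asserts
what those columns actually yield.

## Synthetic scenes

The generator emulates nadir row-crop scenes: per plant, 10–25 planar
elliptical leaves whose inner tips touch the attachment point, azimuths
equally spaced with ±5° jitter, funnel elevation 25°, lengths uniform in a
configurable range (default 150–350 mm, the mature-plant scale; widths
default to half the length), plus an optional sphere tangent to the
attachment point from above (absent in the pre-heading stage). Rendering is
an exact per-pixel z-buffer under the pinhole model (ray-plane and
ray-sphere intersection, no mesh approximation); Gaussian depth noise and a
configurable fraction of uniform outlier pixels model SfM artefacts.
Everything is deterministic given (specs, camera, seed).

Leaves are planar because the length measurement itself ignores curvature —
planar truth makes length recovery exactly testable; a cylindrical-bend flag
exists for robustness experiments only. The generator also records an
*amodal* head label map (the full silhouette, as a human annotator outlines
it through occluding leaves) next to the visible-only map; head-volume
recovery under occlusion is only meaningful against the amodal mask.
`occlude_head` drapes horizontal leaf patches over the head until a target
fraction of the silhouette is hidden, with accept/reject control that lands
within ±3 % of the target.

What the generator does **not** emulate: leaf curvature and serration,
self-occlusion of the funnel at extreme elevations, SfM reconstruction
artefacts beyond noise + outliers (no correlated error fields, no holes),
weed clutter (available behind a flag, off by default), and RGB appearance.
Passing recovery tests therefore demonstrate the geometry pipeline, not
segmentation robustness on real imagery.

## Problem sizes in tests and the acceptance script

Unit and recovery tests run single-plant scenes at 1024² px (the three-plant
integration scene at 1920×1024), 12 leaves per plant, MSAC at 500
iterations — sizes chosen so the full suite exercises every pipeline stage
end to end in about a minute while keeping rasterization error well below
the tolerances under test. The acceptance script regenerates its scenes at
the same sizes from the seed it is given.

## Known limitations

* Leaf length underestimates whenever the true endpoint is occluded; the
  directional effect is tested, not corrected.
* The allometric area is calibrated for cabbage (factor 2.7); other crops
  need their own factor.
* Off-nadir heads bias volume low (see above); the method presumes each
  plant is measured near the image centre.
* The attachment estimate needs ≥ 3 leaves with non-degenerate planes;
  plants below that report an error record.
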