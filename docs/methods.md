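# Methods

## Problem and pipeline

The package estimates the number of adult flies lying on a bright paper
sheet of known physical size from a single photograph. The pipeline has
four stages, each exposed as library functions and wired together by
`flycount.report.count_image`:

1. **Sheet detection** (`flycount.sheet.detect_sheet`). The luminance
   image is thresholded (Otsu); the largest bright connected region is
   taken as the sheet; the four extreme points of its convex hull seed
   the corner estimate, and each corner is refined by intersecting total
   least-squares line fits to the contour points of its two adjacent
   edges. Detection is rejected if no bright region covers 5% of the
   frame (`NoSheetFound`) and is declared ambiguous when the two largest
   candidates differ in area by under 10% (`AmbiguousSheet`). A frame
   with no dark/bright bimodality at all is treated as a full-frame sheet
   when its mean is bright, and as sheet-free when dark.
2. **Rectification** (`flycount.sheet.rectify`). A projective transform
   maps the output raster's outer pixel corners onto the detected
   quadrilateral; the raster is `target_long_side_px` wide (default
   2000, about 0.15 mm/px on A4 — comfortably resolving 2–3 mm flies)
   and its height follows the paper aspect, so
   `mm_per_px = width_mm / width_px`. Corners are ordered canonically
   (landscape, top-left first, clockwise); portrait photographs are
   thereby rotated automatically. Quadrilaterals with a corner angle
   below 20° raise `DegenerateQuad`.
3. **Segmentation** (`flycount.segmentation`). See "Binarisation and
   measurement" below.
4. **Classification and counting** (`flycount.classify`). The size rules
   and defaults (3 mm, 14 mm, 10%, 0.71, 4) described in the README,
   with `floor` as the integer part throughout (all quantities are
   positive).

## Binarisation and measurement

The imaging protocol guarantees high contrast (dark flies, white paper),
but two effects break a naive global Otsu threshold:

* With a few hundred mm-scale flies on a full sheet the foreground is
  ~0.1% of the pixels. Under an illumination gradient of ±15% the paper
  histogram is wider than the paper/fly separation is salient to a
  between-class-variance criterion, and Otsu splits the *paper* into a
  bright and a dark half. The rectified raster is therefore first
  *flat-field normalised*: a coarse illumination field (wide Gaussian on
  a 16× downsampled copy) is divided out, after a median filter whose
  kernel is sized in millimetres (~0.3 mm) so denoising does not depend
  on raster resolution.
* A threshold derived from class means (Otsu, isodata) moves with the
  number of edge-ramp pixels assigned to the object class, which varies
  with blur and resolution and biases object sizes systematically. The
  isodata threshold on the normalised image is therefore refined to the
  midpoint of the two *plateau* levels (median of the background vs
  median of the 2-px-eroded foreground), pinning the boundary at the
  half-intensity crossing.

An all-false mask is returned when the normalised image has no real
bimodality (relative class contrast < 0.25): an empty sheet must not
yield noise speckle. Component interiors are filled before measurement
(specular highlights would otherwise punch holes and bias area
downward), the outer 2 mm of the sheet is forced to background, and
components whose bounding box touches that band are dropped (sheet-edge
shadows otherwise appear as spurious elongated objects). Connectivity is
8-way: legs and bristles produce diagonal pixel chains that 4-way
connectivity would fragment.

**Area** is the pixel count times the pixel's mm² footprint (this is the
quantity the classification factors act on). **Length** is the longer
side of the minimum-area rotated rectangle over the component's outline,
where the outline is the iso-contour of the local intensity patch at the
plateau midpoint, interpolated to sub-pixel positions by marching
squares. Because any two rectifications of the same photograph
interpolate the same underlying field, this caliper is nearly
resolution-invariant (<1% across a 2× scale change), which matters
because the 3/14 mm length cuts act on it; a maximum caliper taken on the
binary mask would jump by a full pixel when a tip pixel flips. For bare
masks without intensity behind them (unit tests, imported masks) the 0.5
iso-contour of the binary patch is used, which makes a 10-px pixel row
measure exactly 10 px. Pixel-count *area*, by contrast, necessarily
retains ~2% per-object jitter across rectification scales; the
scale-consistency test asserts 2% on the mean and 4% per object for area
and 2% per object for length and centroid.

## Conventions

* Trimming is symmetric: `floor(p/100 * n)` objects discarded from each
  tail ("fractions with minimum and maximum values"), matching standard
  trimmed-mean practice (and `scipy.stats.trim_mean`, which the tests
  use as an oracle). If trimming would discard everything the untrimmed
  mean is used.
* Boundary conventions: strict inequalities for garbage (`<`) and
  touching (`>`), so boundary-equal areas are targets; boundary-equal
  lengths are kept.
* Length-excluded objects do not enter the trimmed mean, and an object
  longer than 14 mm is *not* rescued as a touching clump even though a
  large clump can exceed 14 mm — the rule order is fixed, and
  `n_excluded_large` is surfaced in the report so a user can raise
  `max_length_mm` when clumps are expected.
* Coordinates are 0-based, pixel-centre, row-major; the mm origin is the
  rectified sheet's top-left corner.

## Synthetic scenes

`flycount.scene.generate_scene` emulates the prescribed setup: an ISO or
custom sheet, centred in a 4:3 frame at 85% of its width, tilted by a
pinhole projection (default 8°), paper at intensity 235 on background 30,
linear illumination gradient (default span 10%), Gaussian sensor noise
(default SD 3), all randomness from one seed in a documented draw order
(per object: length, aspect, orientation, intensity, position). The sheet
is drawn 2× supersampled and reduced with anti-aliasing so object edges
are photographically soft; hard rasterisation would alias object sizes
by several percent.

A fly is a dark filled body ellipse plus a tangent head blob; an optional
`--shadow` mode attaches a low-contrast gray lobe emulating the
wing-shadow artifact of frozen flies. Default silhouette length is
uniform 3.8–4.4 mm with aspect 0.40–0.46. Two constraints fix these
defaults. First, lengths must stay clear of the 3 mm filter *after*
rasterisation (pointed sub-pixel tips clip up to ~0.5 mm), or ground
truth would be ambiguous — the length filter the method ships with
presumes real fly silhouettes (body plus appendage extent) measure above
3 mm, so the generator's population does too. Second, the implied area
spread (smallest ≈ 0.8× the trimmed mean) must be compatible with the
0.71 trash factor, as any single-age population the rule works on must
be; a wider spread would misclassify the smallest real flies as garbage
by construction.

Touching clusters are compact aggregates, not straight chains (a chain
of four flies would exceed the 14 mm filter, which real clumps of
anaesthetised flies do not): each member attaches tip-first to a random
earlier member with ~0.5 mm overlap depth, rejecting placements that
overlap non-anchor members or spread the clump beyond 8 mm. The union
area of a k-clump is therefore slightly below k times the single-fly
area, and the clump estimator typically returns k or k−1.

Singles are separated by at least 1.5 mm edge-to-edge and kept 5 mm from
the sheet edge; placement is rejection sampling with bounded retries
(`PlacementFailure`), infeasible when the total footprint exceeds 40% of
the sheet.

`degrade_resolution` simulates a lower-resolution capture by
downsampling to the target megapixel count and upsampling back; it
models resolution only, not optics, demosaicing or compression.

What the generator does **not** emulate: wing postures and sex
dimorphism, specular highlights, depth-of-field and lens distortion,
JPEG artifacts, or the near-threshold contrast of real low-end cameras.
Passing tests therefore demonstrate the correctness and calibration of
the measurement chain, not the field robustness of segmentation on
difficult real photographs; in particular, counts remain error-free at a
simulated 1.3 Mpx because synthetic contrast is ideal, so the
resolution-degradation test asserts the error *direction* (no better at
1.3 Mpx than at 8 Mpx; no worse on A5 than on A3 at 1.3 Mpx), which can
hold with ties at zero.

## Benchmark conditions

The accuracy benchmark (`flycount.evaluation.run_benchmark`, also run by
`scripts/acceptance.py`) generates 20 A4 scenes with per-scene fly counts
uniform in 8–325 and default rendering conditions. Contacts are
minimised, as in the fecundity imaging protocol the generator emulates:
2% of flies are placed in 2–3-fly clusters. This fraction follows from
the counting rule's own arithmetic: a 2–3-fly clump has union area 2–3×
the mean, below the touching factor of 4, so it is necessarily counted
as one target; each clustered fly beyond the first is a guaranteed miss,
and a protocol aiming at ~1% error must keep clustering at the
few-percent level. The observed MAPE of ~0.6–0.8% is dominated by
exactly this clump undercount, and the correlation between estimated and
true counts exceeds 0.999.

Problem sizes used by the test suite: the benchmark above; 100 seeds of
50 separated same-size flies at a 1600 px frame for the exactness check;
30 seeds each of 150-fly A3 and A5 scenes rendered at 8 Mpx for the
resolution-direction check; 200 random cases for the statistics oracles.

## Known limitations

* Sheet detection assumes a single sheet photographed without extreme
  camera roll (the four extreme hull directions must hit four distinct
  corners) and no bright clutter comparable to the sheet.
* The area-ratio clump estimator cannot see 2–3-fly clumps under the
  default touching factor; heavy clustering requires either a lower
  factor or physically separating the flies before imaging.
* MAPE uses reference counts in the denominator; a zero reference raises
  `ZeroReference` rather than being skipped (explicit error beats silent
  bias). Kruskal–Wallis uses the chi-square approximation with tie
  correction; p-values are reported to 3 significant figures in the CLI.
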