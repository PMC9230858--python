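# Methods

This note documents the models and procedures implemented in `riblabel`,
the parameters that matter, the design decisions taken where the problem
was genuinely open, and what the synthetic phantom does and does not show
about real data.

## Geometry and intensity conventions

All volumes are arrays indexed `(z, y, x)` under a fixed axial convention:
slice 0 is most superior, rows grow anterior→posterior, columns grow
patient-right→patient-left (radiological display: the patient's left is on
the image's right). DICOM orientation tags and NIfTI affines are converted
to this convention on read, so the laterality rule ("left" rib) and the
anterior/posterior reflection used for sternum erasure are well defined.
Voxel indices are 0-based; all boxes are half-open `[min, max)`.

Display windowing maps HU to 8-bit with window width/level defaulting to
400/40 HU: values at or below `level − width/2` map to 0, at or above
`level + width/2` to 255, linearly in between with half-up rounding. The
mapping is monotone in HU; the clamp boundaries are inclusive on both
ends. In-plane resampling unifies pixel spacing to 0.798 mm by default
(bilinear for intensities, nearest-neighbor for masks and labels — no new
label values can appear); slice spacing is never resampled.

## Intensity-based rib mask

The IIP pipeline runs, in order: binarize → per-slice vertebra matching
and vertebra/sternum erasure → bed/noise cleanup → non-rib exclusion. No
stage ever adds a foreground voxel.

**Binarization.** A voxel is bone iff its windowed value is *strictly*
greater than the threshold (default 140, the middle of the 8-bit range).
The threshold is a fixed constant with a config override; a per-image-mean
mode would be a drop-in alternative but is not the default.

**Template matching.** The score is the exact integer sum of absolute
differences between a template and the image patch under it. The best
(template, position) pair over the search region wins; ties break toward
the smaller template index, then raster order of position — this makes the
full pipeline deterministic. Matching searches the posterior half of the
slice by default (vertebrae are posterior), which also halves the cost;
binary inputs use an integral-image + FFT cross-correlation decomposition
of the SAD map (`|a−b| = a + b − 2ab` for indicator values), rounded back
to exact integers, with a windowed exact fallback for general 8-bit data.

**Detection box and erasure.** The logged vertebral box is the bounding
box of the matched template's *foreground* at the match position, not the
full template footprint: templates carry a background margin so they
strictly contain the vertebra cross-section, and erasing the full
footprint would clip the heads of ribs that attach immediately lateral to
the vertebra. The erase margin `m` therefore defaults to 0 (configurable);
with exact matches on clean masks the foreground box already covers the
vertebra exactly. The sternum is erased as a box of the same extent whose
center row is the vertebral box's center reflected across the body
centroid row ("facing each other" across the midline); the body centroid
is taken from the largest connected non-air region of the windowed slice,
which excludes the detached scanner bed. Both boxes are clipped at slice
borders. Slices whose best SAD score exceeds a configurable ceiling (off
by default) reuse the nearest superior detection.

**Cleanup.** Per slice: morphological opening with a disk of radius 1,
removal of four-connected components smaller than 20 px, and removal of
components whose bounding box reaches into the 10 px posterior border band
(the scanner bed). All three values are invented defaults and
configurable; the band heuristic assumes the bed hugs the posterior image
border, which holds for supine acquisitions.

**Non-rib exclusion.** 2D regions are extracted by raster-seeded
four-connected region growing (seed = first unvisited 255 pixel from
(0,0); growth continues until no neighbor qualifies), then linked across
consecutive slices by ≥1 pixel overlap into 3D objects — "first time of
appearance" is only meaningful for an object tracked across slices. An
object is kept iff, on its first (most superior) slice, at least one pixel
lies within Chebyshev distance 3 px (`contact_margin`) of that slice's
vertebral box. This removes clavicle- and scapula-like bones that never
abut the spine, at the price of discarding a rib whose spinal attachment
was erased — the known failure mode for tiny 12th ribs.

## CNN arm

The sequence labeler accepts a rib mask from any source, so the CNN arm's
contract is mask ingestion plus evaluation: voxel-wise confusion counts
(positive = rib, value 255) and DSC, precision, recall, specificity and
accuracy. A metric with a zero denominator is reported as undefined
(`None`), never as 0. Patient-level k-fold splitting (deterministic given
a seed, each case tested exactly once) supports cross-validated training.

The included U-net is a compact pure-NumPy encoder–decoder: per level two
3×3 convolutions + ReLU, 2×2 max-pooling down, nearest-neighbor upsampling
+ convolution and skip concatenation up, a 1×1 sigmoid head, binary
cross-entropy loss and Adam. Defaults: depth 4, 16 base filters (doubling
per level), batch size 8, at most 300 epochs with early stopping on
validation loss (patience 10), learning rate 1e-3, He initialization from
a seeded generator. Filter counts, loss and optimizer are declared
defaults, all overridable in `UnetConfig`; input dimensions must be
divisible by `2^depth`. The implementation is sized for CPU-scale
experiments (the test suite trains a depth-2, 8-filter net on 32×32
two-blob images in seconds); clinical-scale training is out of scope.

## Sequence labeling

3D region growing includes a voxel iff it is foreground (255) and
face-adjacent (six-connected neighborhood: ±x, ±y, ±z) to a voxel already
in the cluster; membership is a set and independent of traversal order.
Scanning starts on the first (most superior) slice and proceeds in raster
order, so cluster discovery order is ascending first-appearance slice with
ties broken by the raster order of seed voxels. Clusters smaller than 30
voxels (configurable; set 0 to disable) are dropped as noise.

Laterality: a cluster is *left* iff its centroid column exceeds the
midline (ties right), the midline being the mean vertebra-box center
column over all detections, else the volume's center column. Within each
side, clusters sorted by (first slice, seed raster order) receive side
ordinals; pair *i* joins the *i*-th left with the *i*-th right cluster.
Pairing stops at the shorter side; surplus clusters are reported unpaired
with a warning, and more than 12 pairs flags the case (a non-rib object
was likely labeled). How left and right clusters should be matched when
counts differ is genuinely underdetermined; index-wise pairing with
explicit asymmetry warnings was chosen because it never silently shifts
ordinals on the intact side.

The final label volume re-codes pair *i* as label *i* (left) and `P + i`
(right) for `P` pairs — exactly `{1..2P}`, `12 + i` for a full cage;
unpaired clusters stay in the JSON report but are not re-coded. Display
annotations mark each left rib's lateral-most voxel on its first slice
with the pair ordinal.

## Evaluation

Each predicted cluster is matched to the ground-truth region (rib or
named structure) holding the plurality of its voxels; the match must cover
at least 50% of the cluster — the success judgment is visual in origin,
so an operational overlap criterion is required and 50% plurality is the
least committal choice. Errors: a cluster covering ≥50% of two truth ribs
is an *overlapped pair*; a cluster mostly overlapping a non-rib structure
or background is *non-rib labeled*; a truth rib not correctly claimed by
any cluster — including one matched under a wrong ordinal, whose correct
label is then missing — is a *missed rib*. A case succeeds iff no error is
recorded, which makes the three-way classification exhaustive over
failures.

Cohort success rate = 100 · successes / cases, with a normal-approximation
95% CI (`p ± 1.96 √(p(1−p)/n)`) clipped to [0, 100]. The normal
approximation is crude near 0% and 100%; it is reported for orientation,
not inference, and no between-method significance testing is provided.

## Synthetic phantom

The phantom emulates exactly the features the pipeline's contracts rely
on: a soft-tissue body ellipse (≈40 HU) in air (−1000 HU), a constant
posterior midline vertebral column and an anterior sternum (bone, 700 HU),
a bed strip (300 HU) at the posterior border, optional clavicle-/
scapula-like distractor blobs detached from the spine, and 12 bilateral
rib arcs. Ribs are thin elliptical-arc tubes sweeping
posterior→anterior, each spanning 4 slices and starting 6 slices below
its predecessor, posteriorly four-connected to the vertebral column on
their first slice — so first-appearance order equals the anatomical
ordinal by construction. Rib tubes are twice-dilated curves (L1 radius 2),
hence morphologically open with respect to the radius-1 cleanup disk: the
default opening cannot erode a rib voxel, which is what makes exact mask
recovery on a noise-free phantom a meaningful end-to-end check. Variants:
`missing_rib` removes one rib (23 components), `fused_pair` bridges ribs
*i* and *i+1* into one six-connected component via full-arc voxels on the
gap slices — the axial appearance of adjacent true ribs converging at the
same sternal site. Default noise is 0 HU; Gaussian HU noise is available
for robustness experiments only. Generation is deterministic given the
seed, and the generator refuses geometry that would create unintended
rib–rib contact.

What the phantom does **not** emulate: CT physics (beam hardening, kernel
texture, dose noise), partial-volume gradients at bone boundaries,
vertebral shape variation along the column, ribs overlapping in z on the
same side, costal cartilage, and pathological anatomy beyond the two
variants. Passing tests on the phantom therefore demonstrate the
correctness of the algorithmic contracts (connectivity, ordering,
exclusion rules, bookkeeping), not clinical-grade segmentation accuracy:
on real CT the binarization boundary, template variability and rib–scapula
proximity all matter and are exercised here only through the configurable
parameters. In-plane sizes below ~160 px compress the geometry to where
rounding margins touch; the test suite uses 192 px, and the default is
512×512×76 at (1.0, 0.798, 0.798) mm spacing.

## Numerical choices and degenerate inputs

* Window rounding is half-up; SAD scores and confusion counts are exact
  integers; the FFT cross-correlation term is rounded to the nearest
  integer (safe: counts are far below the 2^53 float mantissa).
* All tie-breaks (template index, raster position, raster seed order,
  laterality ties to the right) are fixed, so identical inputs and config
  give bit-identical outputs.
* An all-air volume yields no vertebra detection: the pipeline raises a
  processing error by default or, in `warn` mode, returns an empty mask.
* Empty masks produce empty reports and all-zero label volumes; asymmetric
  cluster counts are reported, never fatal.
* Metrics with zero denominators are `None`; the empty cohort is an error.

## Problem sizes

The test suite runs mostly on 192 px phantoms and small random volumes;
the oracle-equivalence checks use ≥100 random volumes up to 32×32×16
against `scipy.ndimage.label` as the independent reference. The acceptance
script runs the full default 512×512×76 phantom end to end (about one
minute on one CPU). The U-net smoke test trains a micro configuration
(depth 2, 8 filters, 32×32, 50 images) chosen so training converges in
seconds while still exercising the full forward/backward path.

## Known limitations

* The sternum is located only by reflection of the vertebral box; a
  sternum off the vertebral midline column would be partially missed.
* The contact rule can discard a true rib whose only spinal attachment
  falls inside the erased vertebral box (the small-12th-rib failure mode).
* Left/right assignment assumes an approximately midline spine; severe
  scoliosis would break the single-midline model.
* The U-net is CPU-bound NumPy: correct, deterministic and small, but not
  performant at clinical volume sizes.
* The CI method is a normal approximation; exact (Clopper–Pearson)
  intervals are not implemented.
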