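# riblabel

Automatic rib sequence labeling on axial chest CT.

Radiologists reading chest CT constantly anchor findings to a rib number
("fracture of the left 7th rib"), which means counting rib pairs slice by
slice — tedious, repetitive work. `riblabel` automates it: given an axial
CT volume it produces a ribs-only binary mask, objectifies each rib as a
3D connected component, and assigns ordinal labels 1–12 to every bilateral
rib pair, annotating the left-side ribs for display.

The package is aimed at medical-image-analysis researchers and tool
builders who need a transparent, fully classical baseline (no trained
weights required), a drop-in evaluation harness for any rib segmenter, and
a synthetic thorax phantom with voxel-level ground truth for testing.

## Method

1. **Normalization** — HU volumes are display-windowed at width 400 HU /
   level 40 HU and resampled in-plane to 0.798 mm.
2. **Rib mask (IIP arm)** — the windowed stack is binarized at 140 (8-bit),
   keeping bone. On every slice the thoracic vertebra is located by
   template matching with the sum of absolute differences,

   SAD = Σ<sub>(u,v)</sub> | I₁[u,v] − I₂[u,v] |,

   minimized over positions and a library of cropped vertebra templates;
   the vertebral region and the sternum region facing it across the body
   midline are zero-padded away so the rib cage stops being one connected
   bone. Morphological cleanup removes the scanner bed and specks, and 2D
   four-connected region growing (raster-seeded, tracked across slices)
   excludes every bone object not in contact with the vertebral region on
   its first slice of appearance.
3. **Rib mask (CNN arm)** — alternatively, any external segmentation mask
   can be ingested, or a compact U-net (NumPy encoder–decoder with skip
   connections, batch size 8, ≤300 epochs with early stopping) can be
   trained; quality is reported as DSC = 2TP / (2TP + FP + FN), precision,
   recall, specificity and accuracy with patient-level k-fold splits.
4. **Sequence labeling** — 3D region growing over the six-connected
   neighborhood (x, y, z face neighbors) objectifies each rib, seeds taken
   in raster order from the most superior slice. Because ribs slope
   inferiorly, first-appearance order equals the anatomical ordinal: the
   24 clusters of a full rib cage are sorted per body side and paired into
   rib pairs 1–12; the left rib of pair *i* is re-coded to label *i*, the
   right to *12 + i*, and each left rib gets a display annotation.
5. **Evaluation** — a case succeeds when all 12 pairs carry the correct
   ordinal sequence; failures are classified as an overlapped pair, a
   missed rib, or a non-rib bone labeled. Cohort success rates come with a
   95% normal-approximation confidence interval.

## Worked example

```python
import riblabel as rl

spec = rl.PhantomSpec(dims=(None, 192, 192))      # synthetic thorax
vol, truth = rl.generate_phantom(spec)
templates = rl.generate_template_set(spec, 15)
win = rl.apply_window(vol)                        # WW 400 / WL 40
mask = rl.build_iip_mask(win, templates)
labels, report = rl.label_sequence(mask)
print("pairs:", len(report.pairs), "unpaired:", report.unpaired)
print("first three pairs:", report.pairs[:3])
result = rl.case_success(labels, report, truth)
print("case success:", result.success, "errors:", result.errors)
```

prints

```
pairs: 12 unpaired: []
first three pairs: [(1, 2, 1), (2, 4, 3), (3, 6, 5)]
case success: True errors: []
```

Twelve bilateral pairs were found with nothing left unpaired; each pair
entry is `(ordinal, left_cluster_id, right_cluster_id)` — the right rib of
each pair is discovered first because raster scanning reaches the lower
column index first. The case evaluates as a complete, correctly ordered
sequence. On this noise-free phantom the extracted mask equals the
ground-truth rib voxel set exactly (DSC 1.0), with the bed, vertebra,
sternum and a clavicle-like distractor all removed.

The same pipeline is available from the shell:

```bash
riblabel phantom --out-dir case0 --size 192
riblabel label case0/volume.nii.gz --method iip \
    --templates case0/templates --out-dir case0/pred --overlays
riblabel eval --pred case0/pred/labels.nii.gz \
    --report case0/pred/report.json \
    --truth case0/truth_ribs.nii.gz --out case0/eval.json
```

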