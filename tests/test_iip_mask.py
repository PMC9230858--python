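"""IIP mask extraction: binarization, SAD matching, erasure, cleanup,
2D region growing and the non-rib exclusion rule."""

import numpy as np
import pytest
from scipy import ndimage

import riblabel as rl
from riblabel import iip_mask as im
from riblabel.errors import ParameterError, ProcessingError


def _win(arr, spacing=(1.0, 1.0, 1.0)):
    return rl.WindowedVolume(np.asarray(arr, dtype=np.uint8), 400, 40, spacing)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("value,expected", [(139, 0), (140, 0), (141, 255)])
def test_binarize_threshold_is_strictly_greater(value, expected):
    out = rl.binarize(_win(np.full((1, 4, 4), value)), 140)
    assert out.voxels.min() == out.voxels.max() == expected


def test_binarize_phantom_recovers_bone_set(small_phantom):
    vol, truth = small_phantom
    binary = rl.binarize(rl.apply_window(vol))
    np.testing.assert_array_equal(binary.voxels, truth.all_bone_mask().voxels)


def test_binarize_rejects_out_of_range_threshold():
    with pytest.raises(ParameterError):
        rl.binarize(_win(np.zeros((1, 2, 2))), 300)


# ---------------------------------------------------------------------------
# SAD
# ---------------------------------------------------------------------------

def test_sad_identical_patch_is_zero(rng):
    image = rng.integers(0, 256, (20, 20)).astype(np.uint8)
    assert rl.sad(image, image[5:9, 7:12], (5, 7)) == 0


def test_sad_hand_example():
    image = np.zeros((4, 4), dtype=np.uint8)
    image[1:3, 1:3] = [[255, 255], [0, 0]]
    template = np.array([[0, 255], [0, 0]], dtype=np.uint8)
    assert rl.sad(image, template, (1, 1)) == 255


def test_sad_matches_brute_force(rng):
    """SAD equals an explicit double-loop sum on random 8x8 pairs."""
    for _ in range(25):
        image = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        template = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        r, c = rng.integers(0, 5, 2)
        expected = 0
        for i in range(8):
            for j in range(8):
                expected += abs(int(image[r + i, c + j]) - int(template[i, j]))
        assert rl.sad(image, template, (int(r), int(c))) == expected


def test_sad_overhang_rejected():
    with pytest.raises(ParameterError):
        rl.sad(np.zeros((4, 4)), np.zeros((3, 3)), (2, 2))


# ---------------------------------------------------------------------------
# Template matching
# ---------------------------------------------------------------------------

def _brute_match(slice2d, templates):
    best = None
    for idx, tmpl in enumerate(templates.templates):
        th, tw = tmpl.shape
        for r in range(slice2d.shape[0] - th + 1):
            for c in range(slice2d.shape[1] - tw + 1):
                s = rl.sad(slice2d, tmpl, (r, c))
                cand = (s, idx, r, c)
                if best is None or cand < best:
                    best = cand
    return best


def test_match_finds_planted_copy(rng):
    slice2d = np.zeros((400, 400), dtype=np.uint8)
    tmpl = np.where(rng.random((24, 20)) > 0.4, 255, 0).astype(np.uint8)
    slice2d[300:324, 250:270] = tmpl
    decoys = [np.full((10, 10), 255, dtype=np.uint8),
              np.where(rng.random((12, 12)) > 0.5, 255, 0).astype(np.uint8)]
    tset = rl.TemplateSet(decoys + [tmpl.copy()], ["t0", "t1", "t2"])
    det = rl.match_vertebra(slice2d, tset, (200, 0, 400, 400))
    assert det.template_id == "t2"
    assert det.top_left == (300, 250)
    assert det.score == 0


def test_match_all_zero_degenerate_tie():
    tset = rl.TemplateSet([np.zeros((4, 4), dtype=np.uint8)], ["t0"])
    det = rl.match_vertebra(np.zeros((16, 16), dtype=np.uint8), tset)
    assert det.top_left == (0, 0)
    assert det.score == 0


def test_match_equals_brute_force_search(rng):
    """Exhaustive search on 32x32 fixtures, including tie-breaking."""
    for _ in range(5):
        slice2d = np.where(rng.random((32, 32)) > 0.6, 255, 0).astype(np.uint8)
        tset = rl.TemplateSet(
            [np.where(rng.random((7, 6)) > 0.5, 255, 0).astype(np.uint8),
             np.where(rng.random((5, 8)) > 0.5, 255, 0).astype(np.uint8)],
            ["a", "b"])
        det = rl.match_vertebra(slice2d, tset)
        score, idx, r, c = _brute_match(slice2d, tset)
        assert det.score == score
        assert det.template_id == tset.ids[idx]
        assert det.top_left == (r, c)


def test_match_empty_template_set_rejected():
    with pytest.raises(ParameterError):
        rl.TemplateSet([], [])


# ---------------------------------------------------------------------------
# Vertebra/sternum erasure
# ---------------------------------------------------------------------------

def _det(box, z=0):
    return rl.VertebraDetection(z, (box[0], box[1]), "t", 0, box)


def test_erase_removes_only_foreground_in_boxes():
    sl = np.zeros((40, 40), dtype=np.uint8)
    sl[25:30, 15:20] = 255  # vertebra, below centroid
    out, vbox, sbox = rl.erase_vertebra_sternum(sl, _det((25, 15, 30, 20)), 20.0)
    assert out.sum() == 0
    assert vbox == (25, 15, 30, 20)
    # sternum box mirrors across row 20: center 27.5 -> 12.5
    assert sbox == (10, 15, 15, 20)


def test_erase_clips_at_border():
    sl = np.full((20, 20), 255, dtype=np.uint8)
    out, vbox, sbox = rl.erase_vertebra_sternum(sl, _det((18, 18, 24, 24)), 2.0)
    assert vbox == (18, 18, 20, 20)
    assert out[19, 19] == 0
    assert out[0, 0] == 255 or sbox[0] == 0  # no exception; clipped erasure


def test_erase_on_phantom_slice_preserves_ribs(small_phantom, small_templates):
    vol, truth = small_phantom
    win = rl.apply_window(vol)
    binary = rl.binarize(win)
    z = 0  # vertebra + sternum present, no ribs yet
    det = rl.match_vertebra(binary.voxels[z], small_templates,
                            (96, 0, 192, 192), z)
    centroid = im._body_centroid_row(win.voxels[z])
    out, _, _ = rl.erase_vertebra_sternum(binary.voxels[z], det, centroid)
    assert out[truth.structures["vertebra"][z]].sum() == 0
    assert out[truth.structures["sternum"][z]].sum() == 0
    rib_sel = truth.rib_labels[z] > 0
    np.testing.assert_array_equal(out[rib_sel], binary.voxels[z][rib_sel])


# ---------------------------------------------------------------------------
# Bed and noise removal
# ---------------------------------------------------------------------------

def test_remove_noise_drops_small_objects():
    arr = np.zeros((1, 30, 30), dtype=np.uint8)
    arr[0, 5, 5] = 255
    out = rl.remove_bed_and_noise(rl.BinaryVolume(arr, (1, 1, 1)),
                                  min_size=5, opening_radius=0)
    assert out.voxels.sum() == 0


def test_remove_bed_strip_keeps_interior_objects():
    arr = np.zeros((1, 60, 60), dtype=np.uint8)
    arr[0, 55:58, 10:50] = 255          # bed at posterior border band
    arr[0, 20:30, 20:30] = 255          # interior object
    out = rl.remove_bed_and_noise(rl.BinaryVolume(arr, (1, 1, 1)),
                                  min_size=5, opening_radius=0, bed_band=10)
    assert out.voxels[0, 55:58, :].sum() == 0
    assert (out.voxels[0, 20:30, 20:30] == 255).all()


def test_remove_bed_on_empty_volume():
    arr = np.zeros((2, 10, 10), dtype=np.uint8)
    out = rl.remove_bed_and_noise(rl.BinaryVolume(arr, (1, 1, 1)))
    assert out.voxels.sum() == 0


def test_cleanup_never_adds_foreground(small_phantom):
    vol, _ = small_phantom
    binary = rl.binarize(rl.apply_window(vol))
    out = rl.remove_bed_and_noise(binary)
    assert not np.any((out.voxels == 255) & (binary.voxels == 0))


# ---------------------------------------------------------------------------
# 2D region growing
# ---------------------------------------------------------------------------

def test_diagonal_pixels_are_separate_regions():
    sl = np.zeros((4, 4), dtype=np.uint8)
    sl[1, 1] = sl[2, 2] = 255
    regions = rl.extract_slice_objects(sl)
    assert len(regions) == 2
    assert all(r.size == 1 for r in regions)


def test_solid_square_single_region():
    sl = np.zeros((5, 5), dtype=np.uint8)
    sl[1:4, 1:4] = 255
    regions = rl.extract_slice_objects(sl)
    assert len(regions) == 1
    assert regions[0].size == 9
    assert regions[0].seed == (1, 1)


def test_regions_match_connected_component_oracle(rng):
    """Membership, count and raster seed order versus scipy 4-connectivity
    labeling on 50 random sparse slices."""
    structure = ndimage.generate_binary_structure(2, 1)
    for _ in range(50):
        sl = np.where(rng.random((24, 24)) > 0.75, 255, 0).astype(np.uint8)
        regions = rl.extract_slice_objects(sl)
        labels, n = ndimage.label(sl > 0, structure=structure)
        assert len(regions) == n
        seen = set()
        prev_seed = (-1, -1)
        for reg in regions:
            assert reg.seed > prev_seed  # raster order of seeds
            prev_seed = reg.seed
            ids = {labels[y, x] for (y, x) in reg.pixels}
            assert len(ids) == 1  # exactly one oracle component
            oracle_id = ids.pop()
            assert oracle_id not in seen
            seen.add(oracle_id)
            assert reg.size == int((labels == oracle_id).sum())


def test_regions_partition_the_foreground(rng):
    sl = np.where(rng.random((20, 20)) > 0.6, 255, 0).astype(np.uint8)
    regions = rl.extract_slice_objects(sl)
    union = set()
    for reg in regions:
        assert not (union & reg.pixels)  # disjoint
        union |= reg.pixels
    assert union == {tuple(p) for p in np.argwhere(sl == 255)}


# ---------------------------------------------------------------------------
# Non-rib exclusion
# ---------------------------------------------------------------------------

def test_filter_removes_detached_distractor(small_run):
    truth = small_run["truth"]
    mask = small_run["mask"]
    fg = mask.volume.foreground()
    for name, m in truth.structures.items():
        if name.startswith("distractor"):
            assert not fg[m].any(), f"{name} should be excluded"
    assert fg[truth.rib_labels > 0].all()


def test_filter_keeps_mask_with_only_touching_objects():
    vol = np.zeros((3, 20, 20), dtype=np.uint8)
    vol[:, 8:12, 8:12] = 255  # one object adjacent to the vertebra box
    dets = [_det((8, 12, 12, 16), z) for z in range(3)]
    mask = rl.filter_nonrib_objects(rl.BinaryVolume(vol, (1, 1, 1)), dets, 3)
    np.testing.assert_array_equal(mask.volume.voxels, vol)


def test_filter_object_on_last_slice_kept():
    vol = np.zeros((3, 20, 20), dtype=np.uint8)
    vol[2, 5:7, 5:7] = 255
    dets = [_det((5, 8, 9, 12), z) for z in range(3)]
    mask = rl.filter_nonrib_objects(rl.BinaryVolume(vol, (1, 1, 1)), dets, 3)
    assert mask.volume.voxels[2, 5:7, 5:7].min() == 255


def test_filter_requires_detection_for_first_slice():
    vol = np.zeros((3, 20, 20), dtype=np.uint8)
    vol[0, 5:7, 5:7] = 255
    with pytest.raises(ProcessingError, match="slice 0"):
        rl.filter_nonrib_objects(rl.BinaryVolume(vol, (1, 1, 1)),
                                 [_det((5, 8, 9, 12), 2)], 3)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def test_build_iip_mask_recovers_ground_truth(small_run):
    truth = small_run["truth"]
    np.testing.assert_array_equal(small_run["mask"].volume.voxels,
                                  truth.rib_mask().voxels)


def test_pipeline_never_adds_foreground(small_run):
    binary = rl.binarize(small_run["win"])
    fg_out = small_run["mask"].volume.foreground()
    assert not np.any(fg_out & ~binary.foreground())


def test_stage_ablation_consistency(small_templates):
    """Without bed or distractors, disabling the cleanup stages changes
    nothing on a noise-free phantom."""
    spec = rl.PhantomSpec(dims=(None, 192, 192), include_bed=False,
                          distractors=())
    vol, _ = rl.generate_phantom(spec)
    win = rl.apply_window(vol)
    full = rl.build_iip_mask(win, small_templates)
    ablated = rl.build_iip_mask(win, small_templates,
                                rl.IIPConfig(opening_radius=0, min_size=0,
                                             bed_band=0))
    np.testing.assert_array_equal(full.volume.voxels, ablated.volume.voxels)


def test_all_air_volume(small_templates):
    win = rl.WindowedVolume(np.zeros((4, 64, 64), dtype=np.uint8),
                            400, 40, (1, 1, 1))
    with pytest.raises(ProcessingError):
        rl.build_iip_mask(win, small_templates)
    mask = rl.build_iip_mask(win, small_templates,
                             rl.IIPConfig(on_no_vertebra="warn"))
    assert mask.volume.voxels.sum() == 0


def test_detections_logged_per_slice(small_run):
    dets = small_run["mask"].detections
    assert len(dets) == small_run["win"].shape[0]
    # the phantom vertebra cross-section is constant: one box everywhere
    assert len({d.box for d in dets}) == 1
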