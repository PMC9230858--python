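"""Volume I/O: windowing, resampling, NIfTI/DICOM round trips, writers."""

import numpy as np
import pydicom
import pytest
from hypothesis import given, settings, strategies as st
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

import riblabel as rl
from riblabel.errors import FormatError, ParameterError


def _ct(arr, spacing=(1.0, 1.0, 1.0)):
    return rl.CTVolume(np.asarray(arr), spacing)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hu,expected", [
    (-160, 0),      # lower clamp boundary (level - width/2)
    (-200, 0),
    (240, 255),     # upper clamp boundary (level + width/2)
    (500, 255),
    (40, 128),      # midpoint: 255 * 200/400 = 127.5 rounds half-up
    (-159, 1),      # 255/400 = 0.6375 rounds to 1
])
def test_window_mapping_values(hu, expected):
    win = rl.apply_window(_ct(np.full((1, 2, 2), hu)), 400, 40)
    assert win.voxels.min() == win.voxels.max() == expected


def test_window_rejects_nonpositive_width():
    with pytest.raises(ParameterError):
        rl.apply_window(_ct(np.zeros((1, 2, 2))), 0, 40)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(-2000, 3000), st.integers(-2000, 3000))
def test_window_monotone_and_bounded(a, b):
    """The window mapping is monotone non-decreasing in HU, in [0, 255]."""
    vol = _ct(np.array([[[a, b]]]))
    win = rl.apply_window(vol, 400, 40).voxels
    assert 0 <= win.min() and win.max() <= 255
    va, vb = int(win[0, 0, 0]), int(win[0, 0, 1])
    if a <= b:
        assert va <= vb
    else:
        assert va >= vb


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def test_resample_noop_at_target_spacing():
    vol = _ct(np.arange(64).reshape(1, 8, 8), (1.0, 0.798, 0.798))
    out = rl.resample_inplane(vol, 0.798)
    assert out is vol


def test_resample_constant_volume_dims_and_value():
    vol = _ct(np.full((2, 100, 100), 7), (1.0, 0.617, 0.617))
    out = rl.resample_inplane(vol, 0.798)
    expected = round(100 * 0.617 / 0.798)
    assert out.shape == (2, expected, expected)
    assert np.all(out.voxels == 7)
    assert out.spacing == (1.0, 0.798, 0.798)


def test_resample_binary_stays_binary():
    arr = np.where(np.random.default_rng(0).random((2, 40, 40)) > 0.5, 255, 0)
    mask = rl.BinaryVolume(arr.astype(np.uint8), (1.0, 0.617, 0.617))
    out = rl.resample_inplane(mask, 0.798)
    assert set(np.unique(out.voxels)) <= {0, 255}


def test_resample_label_volume_creates_no_new_labels(rng):
    arr = rng.integers(0, 4, (3, 30, 30))
    lab = rl.LabelVolume(arr, (1.0, 1.2, 1.2))
    out = rl.resample_inplane(lab, 0.798)
    assert set(np.unique(out.voxels)) <= set(np.unique(arr))


def test_resample_rejects_nonpositive_target():
    with pytest.raises(ParameterError):
        rl.resample_inplane(_ct(np.zeros((1, 4, 4))), -1.0)


# ---------------------------------------------------------------------------
# NIfTI round trips
# ---------------------------------------------------------------------------

def test_ct_volume_nifti_round_trip(tmp_path, rng):
    arr = rng.integers(-1000, 2000, (5, 16, 12)).astype(np.int32)
    vol = rl.CTVolume(arr, (2.5, 0.7, 0.8))
    path = tmp_path / "vol.nii.gz"
    rl.write_ct_volume(vol, path)
    back = rl.read_ct_volume(path)
    np.testing.assert_array_equal(back.voxels, arr)
    assert np.allclose(back.spacing, vol.spacing)


def test_label_volume_nifti_round_trip(tmp_path, rng):
    arr = rng.integers(0, 5, (4, 10, 10))
    lab = rl.LabelVolume(arr, (1.0, 1.0, 1.0))
    path = tmp_path / "lab.nii.gz"
    rl.write_label_volume(lab, path)
    back = rl.read_label_volume(path)
    np.testing.assert_array_equal(back.voxels, arr)


def test_binary_volume_nifti_round_trip(tmp_path):
    arr = np.zeros((2, 8, 8), dtype=np.uint8)
    arr[1, 2:5, 3:6] = 255
    path = tmp_path / "mask.nii.gz"
    rl.write_binary_volume(rl.BinaryVolume(arr, (1, 1, 1)), path)
    np.testing.assert_array_equal(rl.read_binary_volume(path).voxels, arr)


def test_read_missing_file_is_format_error(tmp_path):
    with pytest.raises(FormatError):
        rl.read_ct_volume(tmp_path / "nope.nii.gz")


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _write_dicom_slice(path, pixels, z, spacing=(0.7, 0.8),
                       orientation=(1, 0, 0, 0, 1, 0)):
    ds = pydicom.Dataset()
    ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.2"  # CT Image Storage
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [spacing[0], spacing[1]]
    ds.ImageOrientationPatient = list(orientation)
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.astype("<u2").tobytes()
    meta = FileMetaDataset()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    ds.file_meta = meta
    ds.save_as(str(path), enforce_file_format=True)


def test_dicom_series_read(tmp_path, rng):
    series = tmp_path / "case"
    series.mkdir()
    raw = rng.integers(0, 3000, (3, 8, 6)).astype(np.uint16)
    # files written inferior-first: reader must sort most superior first
    for i, z in enumerate([10.0, 20.0, 30.0]):
        _write_dicom_slice(series / f"s{i}.dcm", raw[i], z)
    vol = rl.read_ct_volume(series)
    assert vol.shape == (3, 8, 6)
    # slice order: z=30 (most superior) first; HU = raw - 1024
    np.testing.assert_array_equal(vol.voxels[0], raw[2].astype(int) - 1024)
    np.testing.assert_array_equal(vol.voxels[2], raw[0].astype(int) - 1024)
    assert np.allclose(vol.spacing, (10.0, 0.7, 0.8))


def test_dicom_flipped_orientation_is_normalized(tmp_path, rng):
    series = tmp_path / "case"
    series.mkdir()
    raw = rng.integers(0, 3000, (8, 6)).astype(np.uint16)
    _write_dicom_slice(series / "a.dcm", raw, 0.0,
                       orientation=(-1, 0, 0, 0, -1, 0))
    vol = rl.read_ct_volume(series)
    np.testing.assert_array_equal(vol.voxels[0],
                                  raw[::-1, ::-1].astype(int) - 1024)


def test_dicom_corrupt_slice_names_file(tmp_path, rng):
    series = tmp_path / "case"
    series.mkdir()
    _write_dicom_slice(series / "good.dcm", np.zeros((4, 4), dtype=np.uint16), 0.0)
    (series / "bad.dcm").write_bytes(b"this is not dicom")
    with pytest.raises(FormatError, match="bad.dcm"):
        rl.read_ct_volume(series)


def test_dicom_mixed_orientation_rejected(tmp_path):
    series = tmp_path / "case"
    series.mkdir()
    px = np.zeros((4, 4), dtype=np.uint16)
    _write_dicom_slice(series / "a.dcm", px, 0.0, orientation=(1, 0, 0, 0, 1, 0))
    _write_dicom_slice(series / "b.dcm", px, 5.0, orientation=(0, 1, 0, 1, 0, 0))
    with pytest.raises(FormatError, match="orientation"):
        rl.read_ct_volume(series)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def test_overlays_one_png_per_slice(tmp_path, small_run):
    win, labels, report = small_run["win"], small_run["labels"], small_run["report"]
    paths = rl.write_overlays(win, labels, tmp_path / "ov", report.annotations)
    assert len(paths) == win.shape[0]
    assert all(p.exists() for p in paths)


def test_overlays_empty_labels(tmp_path):
    win = rl.WindowedVolume(np.zeros((2, 8, 8), dtype=np.uint8), 400, 40, (1, 1, 1))
    lab = rl.LabelVolume(np.zeros((2, 8, 8), dtype=np.int32), (1, 1, 1))
    paths = rl.write_overlays(win, lab, tmp_path / "ov")
    assert len(paths) == 2


def test_phantom_volume_round_trip(tmp_path, small_phantom):
    vol, _ = small_phantom
    path = tmp_path / "phantom.nii.gz"
    rl.write_ct_volume(vol, path)
    back = rl.read_ct_volume(path)
    np.testing.assert_array_equal(back.voxels, vol.voxels)
    assert np.allclose(back.spacing, vol.spacing)
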