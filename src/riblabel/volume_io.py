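"""CT volume I/O, intensity windowing, in-plane resampling and result writers.

All volumes use a fixed axial array convention, indexed ``(z, y, x)``:

* slice 0 is the most superior slice;
* rows (``y``) increase anterior -> posterior (the patient's front is at the
  top of the image);
* columns (``x``) increase patient-right -> patient-left, i.e. the patient's
  left side appears on the right of the image (radiological display).

DICOM orientation tags and NIfTI affines are honored on read and converted
to this convention, so every downstream stage (vertebra/sternum geometry,
left/right laterality) can rely on it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import nibabel as nib
import pydicom
from PIL import Image, ImageDraw
from scipy import ndimage

from .errors import FormatError, ParameterError

# Display window unified across all cases: width 400 HU, level 40 HU.
DEFAULT_WINDOW_WIDTH = 400.0
DEFAULT_WINDOW_LEVEL = 40.0
# In-plane pixel spacing every case is reformatted to (mm).
DEFAULT_PIXEL_SPACING = 0.798


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ParameterError(f"spacing must be 3 strictly positive values, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3D CT stack in Hounsfield units under the fixed axial convention."""

    voxels: np.ndarray  # (z, y, x) integer HU
    spacing: tuple[float, float, float]  # (z, y, x) mm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ParameterError("CTVolume requires a 3D array with at least one slice")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class WindowedVolume:
    """An 8-bit display-windowed volume; derived deterministically from HU."""

    voxels: np.ndarray  # (z, y, x) in [0, 255]
    window_width: float
    window_level: float
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = _check_spacing(self.spacing)
        if self.voxels.size and (self.voxels.min() < 0 or self.voxels.max() > 255):
            raise ParameterError("WindowedVolume voxels must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryVolume:
    """A volume over {0, 255}; 255 marks foreground (bone)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = _check_spacing(self.spacing)
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 255))):
            raise ParameterError("BinaryVolume voxels must be exactly 0 or 255")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def foreground(self) -> np.ndarray:
        """Boolean view of the 255 voxels."""
        return self.voxels == 255


@dataclass
class LabelVolume:
    """Non-negative integer labels per voxel; 0 is background and nonzero
    labels form the contiguous set {1..label_count}."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label_count: int = field(default=-1)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = _check_spacing(self.spacing)
        labels = np.unique(self.voxels)
        labels = labels[labels != 0]
        if labels.size and labels.min() < 0:
            raise ParameterError("LabelVolume labels must be non-negative")
        expected = set(range(1, labels.size + 1))
        if set(int(v) for v in labels) != expected:
            raise ParameterError(
                "nonzero labels must be contiguous {1..label_count}, got "
                f"{sorted(int(v) for v in labels)}"
            )
        if self.label_count == -1:
            self.label_count = int(labels.size)
        elif self.label_count != labels.size:
            raise ParameterError("label_count inconsistent with voxel labels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Reorient a NIfTI image into the (z, y, x) axial convention."""
    img = nib.as_closest_canonical(img)  # voxel axes -> (+R, +A, +S)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    # canonical (R, A, S) -> ours (inferior-growing z, posterior-growing y,
    # left-growing x): transpose then flip every axis.
    arr = np.ascontiguousarray(data.transpose(2, 1, 0)[::-1, ::-1, ::-1])
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return arr, spacing


_AXIAL_DIRS = {
    (1, 0, 0): ("x", 1), (-1, 0, 0): ("x", -1),
    (0, 1, 0): ("y", 1), (0, -1, 0): ("y", -1),
}


def _read_dicom_series(directory: Path) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"no files in DICOM directory {directory}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
            _ = ds.pixel_array
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise FormatError(f"cannot read DICOM slice {f.name}: {exc}") from exc
        slices.append((f, ds))

    orientations = {tuple(round(float(v)) for v in ds.ImageOrientationPatient)
                    for _, ds in slices}
    if len(orientations) != 1:
        raise FormatError("mixed image orientations in DICOM series")
    iop = list(orientations)[0]
    row_dir, col_dir = tuple(iop[:3]), tuple(iop[3:])
    if row_dir not in _AXIAL_DIRS or col_dir not in _AXIAL_DIRS:
        raise FormatError(f"unsupported (non-axial) orientation {row_dir}+{col_dir}")
    c_axis, c_sign = _AXIAL_DIRS[row_dir]   # direction columns advance in
    r_axis, r_sign = _AXIAL_DIRS[col_dir]   # direction rows advance in
    if {c_axis, r_axis} != {"x", "y"}:
        raise FormatError("DICOM in-plane axes must span patient x and y")

    # Slice normal is +/-z for an axial series; sort most superior (+z) first.
    positions = []
    for f, ds in slices:
        try:
            positions.append(float(ds.ImagePositionPatient[2]))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"slice {f.name} lacks ImagePositionPatient") from exc
    order = np.argsort(positions)[::-1]
    slices = [slices[i] for i in order]
    positions = [positions[i] for i in order]

    shape0 = slices[0][1].pixel_array.shape
    planes = []
    for f, ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        if arr.shape != shape0:
            raise FormatError(f"slice {f.name} has inconsistent dimensions")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = arr * slope + inter
        # Target: rows -> +y (posterior), columns -> +x (patient left).
        if r_axis == "y":
            ysign, xsign = r_sign, c_sign
        else:  # rows advance along patient x: transpose in-plane first
            hu = hu.T
            ysign, xsign = c_sign, r_sign
        if ysign < 0:
            hu = hu[::-1, :]
        if xsign < 0:
            hu = hu[:, ::-1]
        planes.append(hu)

    if len(slices) > 1:
        dz = np.abs(np.diff(positions))
        if dz.max() - dz.min() > 0.01 * max(dz.max(), 1e-9):
            raise FormatError("inconsistent slice spacing in DICOM series")
        z_spacing = float(dz.mean())
    else:
        z_spacing = float(getattr(slices[0][1], "SliceThickness", 1.0) or 1.0)
    ps = slices[0][1].PixelSpacing  # (row spacing, column spacing)
    y_spacing, x_spacing = float(ps[0]), float(ps[1])
    if r_axis != "y":
        y_spacing, x_spacing = x_spacing, y_spacing
    vol = np.rint(np.stack(planes)).astype(np.int32)
    return CTVolume(vol, (z_spacing, y_spacing, x_spacing))


def read_ct_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume (DICOM series directory or NIfTI file) into HU."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if not path.exists():
        raise FormatError(f"no such input: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    arr, spacing = _from_nifti(img)
    return CTVolume(np.rint(arr).astype(np.int32), spacing)


def _read_integer_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    arr, spacing = _from_nifti(img)
    return np.rint(arr).astype(np.int64), spacing


def read_binary_volume(path: str | os.PathLike) -> BinaryVolume:
    """Read a {0,255} (or {0,1}, promoted) mask from NIfTI."""
    arr, spacing = _read_integer_nifti(path)
    vals = set(np.unique(arr).tolist())
    if vals <= {0, 1}:
        arr = arr * 255
    return BinaryVolume(arr.astype(np.uint8), spacing)


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    arr, spacing = _read_integer_nifti(path)
    return LabelVolume(arr.astype(np.int32), spacing)


# ---------------------------------------------------------------------------
# Windowing and resampling
# ---------------------------------------------------------------------------

def apply_window(vol: CTVolume,
                 width: float = DEFAULT_WINDOW_WIDTH,
                 level: float = DEFAULT_WINDOW_LEVEL) -> WindowedVolume:
    """Map HU to 8-bit display values with a linear window.

    HU at or below ``level - width/2`` map to 0, at or above
    ``level + width/2`` map to 255, linearly in between with half-up
    rounding, so the mapping is monotone non-decreasing in HU.
    """
    if width <= 0:
        raise ParameterError(f"window width must be positive, got {width}")
    lo = level - width / 2.0
    hu = vol.voxels.astype(np.float64)
    scaled = 255.0 * (hu - lo) / width
    out = np.floor(scaled + 0.5)  # round half-up
    out = np.clip(out, 0, 255).astype(np.uint8)
    return WindowedVolume(out, float(width), float(level), vol.spacing)


def resample_inplane(vol, target_spacing: float = DEFAULT_PIXEL_SPACING):
    """Resample each axial slice to ``target_spacing`` mm in-plane.

    z spacing is never changed (cases are reformatted in pixel spacing only).
    Intensity volumes use bilinear interpolation; BinaryVolume and
    LabelVolume use nearest-neighbor so no new label values appear.  Returns
    the input object unchanged (same instance) when it is already at the
    target spacing.
    """
    if target_spacing <= 0:
        raise ParameterError(f"target_spacing must be positive, got {target_spacing}")
    sz, sy, sx = vol.spacing
    if sy == target_spacing and sx == target_spacing:
        return vol
    zoom = (1.0, sy / target_spacing, sx / target_spacing)
    new_spacing = (sz, target_spacing, target_spacing)
    if isinstance(vol, (BinaryVolume, LabelVolume)):
        out = ndimage.zoom(vol.voxels, zoom, order=0, mode="nearest")
        if isinstance(vol, BinaryVolume):
            return BinaryVolume(out, new_spacing)
        return LabelVolume(out, new_spacing)
    out = ndimage.zoom(vol.voxels.astype(np.float64), zoom, order=1, mode="nearest")
    out = np.rint(out).astype(vol.voxels.dtype)
    if isinstance(vol, WindowedVolume):
        return WindowedVolume(np.clip(out, 0, 255).astype(np.uint8),
                              vol.window_width, vol.window_level, new_spacing)
    return CTVolume(out, new_spacing)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _to_nifti(arr: np.ndarray, spacing: tuple[float, float, float]) -> nib.Nifti1Image:
    sz, sy, sx = spacing
    # NIfTI axes (i,j,k) point (left, posterior, inferior) under this LPI
    # affine, matching the (x, y, z) senses of the array directly.
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    affine = np.diag([-sx, -sy, -sz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    return img


def write_ct_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    nib.save(_to_nifti(vol.voxels.astype(np.int16), vol.spacing), str(path))


def write_binary_volume(vol: BinaryVolume, path: str | os.PathLike) -> None:
    nib.save(_to_nifti(vol.voxels.astype(np.uint8), vol.spacing), str(path))


def write_label_volume(lab: LabelVolume, path: str | os.PathLike) -> None:
    dtype = np.uint8 if lab.label_count < 256 else np.uint16
    nib.save(_to_nifti(lab.voxels.astype(dtype), lab.spacing), str(path))


def write_int_volume(arr: np.ndarray, spacing: tuple[float, float, float],
                     path: str | os.PathLike) -> None:
    """Write an arbitrary non-negative integer array (e.g. ground-truth
    labels that need not be contiguous) as a NIfTI volume."""
    dtype = np.uint8 if arr.max(initial=0) < 256 else np.uint16
    nib.save(_to_nifti(np.asarray(arr).astype(dtype), _check_spacing(spacing)),
             str(path))


def write_report(report, path: str | os.PathLike) -> None:
    """Serialize any report object exposing ``to_dict`` (or a plain dict)."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _label_palette(n: int) -> list[tuple[int, int, int]]:
    import colorsys
    out = []
    for i in range(max(n, 1)):
        h = (i * 0.61803398875) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.85, 1.0)
        out.append((int(r * 255), int(g * 255), int(b * 255)))
    return out


def write_overlays(win: WindowedVolume, lab: LabelVolume,
                   directory: str | os.PathLike,
                   annotations: Sequence[tuple[int, int, int, int]] = ()) -> list[Path]:
    """Write one PNG per slice with colored labels over the windowed image.

    ``annotations`` are ``(z, y, x, ordinal)`` display positions; the ordinal
    number is rendered near each annotated (left-side) rib.
    """
    if win.shape != lab.shape:
        raise ParameterError("windowed volume and label volume geometry differ")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    palette = _label_palette(lab.label_count)
    by_slice: dict[int, list[tuple[int, int, int]]] = {}
    for z, y, x, ordinal in annotations:
        by_slice.setdefault(int(z), []).append((int(y), int(x), int(ordinal)))
    paths = []
    for z in range(win.shape[0]):
        base = np.stack([win.voxels[z]] * 3, axis=-1).astype(np.uint8)
        labels = lab.voxels[z]
        for lbl in np.unique(labels):
            if lbl == 0:
                continue
            base[labels == lbl] = palette[(int(lbl) - 1) % len(palette)]
        img = Image.fromarray(base)
        draw = ImageDraw.Draw(img)
        for y, x, ordinal in by_slice.get(z, []):
            draw.text((min(x + 3, img.width - 12), max(y - 10, 0)),
                      str(ordinal), fill=(255, 255, 0))
        out = directory / f"slice_{z:04d}.png"
        img.save(out)
        paths.append(out)
    return paths
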