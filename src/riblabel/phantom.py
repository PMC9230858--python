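"""Synthetic axial thorax phantoms with voxel-level ground truth.

The phantom emulates the anatomy the rib-labeling pipeline relies on: a
soft-tissue body ellipse in air, a posterior midline vertebral column, an
anterior sternum over the upper thoracic slices, 12 bilateral rib arcs that
attach posteriorly next to the vertebra and slope inferiorly (so the
first-appearance order from the top slice equals the anatomical ordinal),
a scanner-bed strip at the posterior image border, and optional distractor
bones (clavicle- or scapula-like blobs) detached from the vertebral region.

Variants reproduce the known failure modes: a missing 12th rib and a fused
pair where rib i and rib i+1 merge into one six-connected component (the
axial appearance of adjacent true ribs converging at the same sternal
site).  Ribs are thin elliptical-arc tubes; geometric realism is bounded —
the target is exercising the pipeline's contracts, not photorealism.

Every rib tube is a twice-dilated (diamond radius 2) curve, i.e. it is
morphologically open with respect to the radius-1 disk, so the default
cleanup opening never erodes a rib voxel on a noise-free phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import ndimage

from .errors import ParameterError
from .iip_mask import TemplateSet, binarize
from .volume_io import BinaryVolume, CTVolume, apply_window

# In-plane geometry as fractions of the slice dimensions.
_BODY_AY, _BODY_AX = 0.36, 0.40       # body ellipse semi-axes
_RIB_RY, _RIB_RX = 0.21, 0.30         # rib arc semi-axes
_VERT_H, _VERT_W = 0.07, 0.06         # vertebra box size
_VERT_OFFSET = 0.20                   # vertebra center row below body center
_STERN_H, _STERN_W = 0.024, 0.043     # sternum box size (fits the mirror box)
_THETA_P, _THETA_A = 0.15, 2.35       # rib arc angular range (posterior->anterior)
_THETA_OVERLAP = 0.08                 # angular overlap between consecutive slices

_DIAMOND = ndimage.generate_binary_structure(2, 1)


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic thorax."""

    dims: tuple[Optional[int], int, int] = (None, 512, 512)  # (z or auto, y, x)
    spacing: tuple[float, float, float] = (1.0, 0.798, 0.798)
    n_pairs: int = 12
    rib_span: int = 4        # slices each rib occupies
    rib_step: int = 6        # slice offset between consecutive ordinals
    z0: int = 4              # first slice of rib pair 1
    include_bed: bool = True
    include_vertebra: bool = True
    distractors: tuple[str, ...] = ("clavicle",)
    missing_rib: Optional[tuple[str, int]] = None   # (side, ordinal)
    fused_pair: Optional[int] = None                # ordinal i fused with i+1
    fused_side: str = "left"
    noise_sd: float = 0.0    # HU; 0 keeps binarization exactly on truth
    bone_hu: int = 700
    soft_hu: int = 40
    air_hu: int = -1000
    bed_hu: int = 300
    seed: int = 0

    @property
    def nz(self) -> int:
        if self.dims[0] is not None:
            return int(self.dims[0])
        return self.z0 + self.rib_step * (self.n_pairs - 1) + self.rib_span + 2

    def rib_z_range(self, ordinal: int) -> tuple[int, int]:
        start = self.z0 + self.rib_step * (ordinal - 1)
        return start, start + self.rib_span

    @classmethod
    def from_file(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        for key in ("dims", "spacing", "distractors", "missing_rib"):
            if key in known and known[key] is not None:
                known[key] = tuple(known[key])
        return cls(**known)

    def to_file(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["dims"] = list(self.dims)
        data["spacing"] = list(self.spacing)
        data["distractors"] = list(self.distractors)
        if data["missing_rib"] is not None:
            data["missing_rib"] = list(data["missing_rib"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class PhantomTruth:
    """Ground truth: per-voxel rib labels and per-structure masks.

    ``rib_labels`` codes left ordinal i as i and right ordinal i as
    n_pairs + i; ``rib_info`` maps each label to its (side, ordinal).
    """

    rib_labels: np.ndarray
    rib_info: dict[int, tuple[str, int]]
    structures: dict[str, np.ndarray]  # vertebra, sternum, bed, distractor_*
    spacing: tuple[float, float, float]
    n_pairs: int

    def rib_mask(self) -> BinaryVolume:
        return BinaryVolume(np.where(self.rib_labels > 0, 255, 0).astype(np.uint8),
                            self.spacing)

    def all_bone_mask(self) -> BinaryVolume:
        fg = self.rib_labels > 0
        for m in self.structures.values():
            fg = fg | m
        return BinaryVolume(np.where(fg, 255, 0).astype(np.uint8), self.spacing)


def _vertebra_box(ny: int, nx: int) -> tuple[int, int, int, int]:
    hv = max(3, round(_VERT_H * ny))
    wv = max(3, round(_VERT_W * nx))
    rv = round(ny / 2 + _VERT_OFFSET * ny)
    cx = nx // 2
    return (rv - hv // 2, cx - wv // 2, rv - hv // 2 + hv, cx - wv // 2 + wv)


def _stamp_curve(plane: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> None:
    ny, nx = plane.shape
    r = np.clip(np.rint(rows).astype(int), 0, ny - 1)
    c = np.clip(np.rint(cols).astype(int), 0, nx - 1)
    plane[r, c] = True


def _rib_plane(spec: PhantomSpec, side: str, theta0: float, theta1: float,
               with_neck: bool) -> np.ndarray:
    """One rib's tube cross-section on one slice (boolean plane)."""
    _, ny, nx = spec.dims[0] or 0, spec.dims[1], spec.dims[2]
    cy, cx = ny / 2.0, nx / 2.0
    ry, rx = _RIB_RY * ny, _RIB_RX * nx
    sigma = 1.0 if side == "left" else -1.0
    plane = np.zeros((ny, nx), dtype=bool)
    n_steps = max(8, int((theta1 - theta0) * max(ry, rx) * 2))
    theta = np.linspace(theta0, theta1, n_steps)
    _stamp_curve(plane, cy + ry * np.cos(theta), cx + sigma * rx * np.sin(theta))
    if with_neck:
        r0, c0, r1, c1 = _vertebra_box(ny, nx)
        rv = (r0 + r1) / 2.0
        # neck start stays 2 px clear of the box so the dilated tube touches
        # (is 4-adjacent to) the vertebra without entering the erased box
        neck_c = (c1 + 2) if side == "left" else (c0 - 3)
        start_r, start_c = cy + ry * np.cos(theta0), cx + sigma * rx * np.sin(theta0)
        n = max(4, int(2 * max(abs(start_r - rv), abs(start_c - neck_c))))
        _stamp_curve(plane, np.linspace(rv, start_r, n), np.linspace(neck_c, start_c, n))
    # two diamond dilations: tube of L1 radius 2, open w.r.t. the radius-1 disk
    plane = ndimage.binary_dilation(plane, _DIAMOND, iterations=2)
    # at small image sizes the dilation margin can graze the vertebral box;
    # the tube spine stays outside it, so clearing keeps the rib connected
    r0, c0, r1, c1 = _vertebra_box(ny, nx)
    plane[r0:r1, c0:c1] = False
    return plane


def _disk_blob(ny: int, nx: int, center: tuple[float, float], radius: int) -> np.ndarray:
    yy, xx = np.ogrid[:ny, :nx]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Rasterize the phantom; deterministic given ``spec.seed``."""
    nz, ny, nx = spec.nz, spec.dims[1], spec.dims[2]
    spec = PhantomSpec(**{**{k: getattr(spec, k) for k in spec.__dataclass_fields__},
                          "dims": (nz, ny, nx)})
    cy, cx = ny / 2.0, nx / 2.0
    if spec.n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    if spec.rib_step <= spec.rib_span and spec.fused_pair is None:
        raise ParameterError("rib_step must exceed rib_span to keep ribs disjoint")

    hu = np.full((nz, ny, nx), spec.air_hu, dtype=np.int32)
    yy, xx = np.ogrid[:ny, :nx]
    body = (((yy - cy) / (_BODY_AY * ny)) ** 2
            + ((xx - cx) / (_BODY_AX * nx)) ** 2) <= 1.0
    hu[:, body] = spec.soft_hu

    structures: dict[str, np.ndarray] = {}
    r0, c0, r1, c1 = _vertebra_box(ny, nx)
    if spec.include_vertebra:
        vertebra = np.zeros((nz, ny, nx), dtype=bool)
        vertebra[:, r0:r1, c0:c1] = True
        structures["vertebra"] = vertebra

    sh = max(2, round(_STERN_H * ny))
    sw = max(2, round(_STERN_W * nx))
    srv = round(ny - (r0 + r1) / 2.0 - sh / 2.0)  # mirror of vertebra center
    sternum = np.zeros((nz, ny, nx), dtype=bool)
    sternum[: nz // 2, srv:srv + sh, int(cx) - sw // 2:int(cx) - sw // 2 + sw] = True
    structures["sternum"] = sternum

    if spec.include_bed:
        bed = np.zeros((nz, ny, nx), dtype=bool)
        bed[:, ny - 8:ny - 5, round(0.2 * nx):round(0.8 * nx)] = True
        structures["bed"] = bed

    for i, kind in enumerate(spec.distractors):
        blob = np.zeros((nz, ny, nx), dtype=bool)
        if kind == "clavicle":
            center = (cy - 0.22 * ny, cx + 0.22 * nx)
            blob[0:4, :, :] = _disk_blob(ny, nx, center, max(3, round(0.02 * nx)))
        elif kind == "scapula":
            center = (cy + 0.24 * ny, cx - 0.26 * nx)
            blob[2:8, :, :] = _disk_blob(ny, nx, center, max(3, round(0.018 * nx)))
        else:
            raise ParameterError(f"unknown distractor kind {kind!r}")
        structures[f"distractor_{i}_{kind}"] = blob

    # Ribs, superior to inferior, so first appearance equals the ordinal.
    rib_labels = np.zeros((nz, ny, nx), dtype=np.int32)
    rib_info: dict[int, tuple[str, int]] = {}
    dtheta = (_THETA_A - _THETA_P) / spec.rib_span
    for ordinal in range(1, spec.n_pairs + 1):
        z_start, z_stop = spec.rib_z_range(ordinal)
        if z_stop > nz:
            raise ParameterError(f"rib {ordinal} does not fit in {nz} slices")
        for side in ("left", "right"):
            if spec.missing_rib == (side, ordinal):
                continue
            label = ordinal if side == "left" else spec.n_pairs + ordinal
            rib_info[label] = (side, ordinal)
            for s, z in enumerate(range(z_start, z_stop)):
                t0 = max(_THETA_P, _THETA_P + s * dtheta - _THETA_OVERLAP)
                t1 = min(_THETA_A, _THETA_P + (s + 1) * dtheta + _THETA_OVERLAP)
                plane = _rib_plane(spec, side, t0, t1, with_neck=(s == 0))
                clash = rib_labels[z][plane]
                if np.any((clash != 0) & (clash != label)):
                    raise ParameterError(
                        f"rib {side} {ordinal} collides with another rib on slice {z}")
                rib_labels[z][plane] = label
        if spec.fused_pair == ordinal:
            # bridge the gap slices with the full arc, owned by rib `ordinal`
            side = spec.fused_side
            label = ordinal if side == "left" else spec.n_pairs + ordinal
            nxt_start, _ = spec.rib_z_range(ordinal + 1)
            for z in range(z_stop, min(nxt_start, nz)):
                plane = _rib_plane(spec, side, _THETA_P, _THETA_A, with_neck=False)
                rib_labels[z][plane] = label

    # Structures must stay pairwise disjoint and clear of the ribs.
    occupancy = (rib_labels > 0).astype(np.int8)
    for name, m in structures.items():
        if np.any(occupancy[m]):
            raise ParameterError(f"structure {name} overlaps another structure")
        occupancy[m] += 1

    bone = rib_labels > 0
    for name, m in structures.items():
        hu[m] = spec.bed_hu if name == "bed" else spec.bone_hu
        if name != "bed":
            bone = bone | m
    hu[rib_labels > 0] = spec.bone_hu

    # The fused/missing variants legitimately change the component count.
    expected = len(rib_info) - (1 if spec.fused_pair is not None else 0)
    _, n_found = ndimage.label(rib_labels > 0,
                               structure=ndimage.generate_binary_structure(3, 1))
    if n_found != expected:
        raise ParameterError(
            f"unintended rib-rib contact: {n_found} rib components, expected {expected}")

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = np.rint(hu + rng.normal(0.0, spec.noise_sd, hu.shape)).astype(np.int32)

    truth = PhantomTruth(rib_labels, rib_info, structures,
                         tuple(spec.spacing), spec.n_pairs)
    return CTVolume(hu, tuple(spec.spacing)), truth


def generate_template_set(spec: PhantomSpec, n_templates: int = 15) -> TemplateSet:
    """Crop windowed-and-binarized vertebra patches from the phantom.

    Patches are taken (with a 2-pixel background margin, so they strictly
    contain the vertebra cross-section) from slices whose crop window holds
    nothing but vertebra, spread evenly over the stack.
    """
    vol, truth = generate_phantom(spec)
    if "vertebra" not in truth.structures or not truth.structures["vertebra"].any():
        raise ParameterError("phantom spec contains no vertebra column")
    binary = binarize(apply_window(vol))
    nz, ny, nx = binary.shape
    r0, c0, r1, c1 = _vertebra_box(ny, nx)
    pad = 2
    win = (slice(max(r0 - pad, 0), min(r1 + pad, ny)),
           slice(max(c0 - pad, 0), min(c1 + pad, nx)))
    non_vertebra = (truth.rib_labels > 0)
    for name, m in truth.structures.items():
        if name != "vertebra":
            non_vertebra = non_vertebra | m
    valid = [z for z in range(nz)
             if truth.structures["vertebra"][z].any()
             and not non_vertebra[(z, *win)].any()]
    if n_templates > len(valid):
        raise ParameterError(
            f"requested {n_templates} templates but only {len(valid)} clean slices")
    picks = [valid[i] for i in
             np.linspace(0, len(valid) - 1, n_templates).round().astype(int)]
    patches = [binary.voxels[(z, *win)].copy() for z in picks]
    return TemplateSet(patches, [f"z{z:03d}" for z in picks])
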