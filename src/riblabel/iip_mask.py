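"""Intensity-based image processing (IIP) rib mask extraction.

The pipeline turns a windowed axial CT stack into a ribs-only binary mask
using classical image processing alone, in this order:

1. global binarization at a fixed 8-bit threshold (default 140) keeping
   only bone;
2. per-slice template matching by the sum of absolute differences (SAD)
   locates the thoracic vertebra;
3. zero-padding erases the vertebral region and the sternum region facing
   it across the body midline, so the rib cage no longer forms one
   connected bone;
4. morphological cleanup removes the scanner bed and small specks;
5. raster-seeded 2D four-connected region growing objectifies the
   remaining bones, regions are tracked across slices into 3D objects, and
   every object not in contact with the vertebral region on its first slice
   of appearance (clavicle, scapula, ...) is excluded.

The SAD score for a template ``I2`` placed on the image ``I1`` at offset
``(u, v)`` is ``sum(|I1[u+i, v+j] - I2[i, j]|)`` over the template extent;
0 means an exact match.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.morphology import disk

from .errors import ParameterError, ProcessingError
from .volume_io import BinaryVolume, WindowedVolume

DEFAULT_THRESHOLD = 140  # 8-bit bone threshold: keep strictly greater values

# 4-connected (in-plane) structuring element for cleanup labeling.
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class TemplateSet:
    """A library of cropped vertebra appearance patches (8-bit, 2D)."""

    templates: list[np.ndarray]
    ids: list[str]

    def __post_init__(self) -> None:
        if not self.templates:
            raise ParameterError("TemplateSet must contain at least one template")
        if len(self.ids) != len(self.templates):
            raise ParameterError("ids and templates length mismatch")
        self.templates = [np.asarray(t, dtype=np.uint8) for t in self.templates]
        for t in self.templates:
            if t.ndim != 2:
                raise ParameterError("templates must be 2D patches")


def load_template_set(directory: str | Path) -> TemplateSet:
    """Load a TemplateSet from a directory of 8-bit grayscale PNGs,
    ordered by filename."""
    directory = Path(directory)
    files = sorted(directory.glob("*.png"))
    if not files:
        raise ParameterError(f"no PNG templates found in {directory}")
    templates = [np.asarray(Image.open(f).convert("L")) for f in files]
    return TemplateSet(templates, [f.stem for f in files])


def save_template_set(templates: TemplateSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, (patch, tid) in enumerate(zip(templates.templates, templates.ids)):
        Image.fromarray(patch).save(directory / f"{i:02d}_{tid}.png")


@dataclass
class VertebraDetection:
    """Best template match on one slice.

    ``top_left`` is the (row, col) origin of the matched template; ``box``
    is the half-open (r0, c0, r1, c1) bounding box of the template's
    foreground at that position — the vertebral region that gets erased.
    """

    slice_index: int
    top_left: tuple[int, int]
    template_id: str
    score: int
    box: tuple[int, int, int, int]


@dataclass
class Region2D:
    """A four-connected foreground region on one slice, in seed raster order."""

    slice_index: int
    pixels: set
    seed: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class RibMask:
    """A ribs-only binary volume plus the provenance of everything removed."""

    volume: BinaryVolume
    detections: list = field(default_factory=list)
    removed: list = field(default_factory=list)


@dataclass
class IIPConfig:
    """Tunables of the IIP pipeline (all distances in pixels)."""

    threshold: int = DEFAULT_THRESHOLD
    contact_margin: int = 3      # Chebyshev distance to the vertebra box
    erase_margin: int = 0        # expansion of the erased boxes
    bed_band: int = 10           # posterior border band height for bed removal
    opening_radius: int = 1      # disk radius of the per-slice opening
    min_size: int = 20           # 2D components smaller than this are noise
    sad_ceiling: Optional[int] = None  # scores above reuse the superior slice
    search: str = "posterior"    # 'posterior' half or 'full' slice search
    on_no_vertebra: str = "raise"  # or 'warn': behaviour with no detection

    @classmethod
    def from_file(cls, path: str | Path) -> "IIPConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def binarize(win: WindowedVolume, threshold: int = DEFAULT_THRESHOLD) -> BinaryVolume:
    """Keep voxels strictly above ``threshold`` as 255; fill the rest with 0."""
    if not 0 <= threshold <= 255:
        raise ParameterError(f"threshold must be in [0, 255], got {threshold}")
    out = np.where(win.voxels > threshold, 255, 0).astype(np.uint8)
    return BinaryVolume(out, win.spacing)


# ---------------------------------------------------------------------------
# SAD template matching
# ---------------------------------------------------------------------------

def sad(image: np.ndarray, template: np.ndarray, origin: tuple[int, int]) -> int:
    """Exact integer sum of absolute differences of ``template`` placed on
    ``image`` with its top-left corner at ``origin`` (row, col)."""
    image = np.asarray(image)
    template = np.asarray(template)
    r, c = origin
    th, tw = template.shape
    if r < 0 or c < 0 or r + th > image.shape[0] or c + tw > image.shape[1]:
        raise ParameterError(f"template at {origin} overhangs the image")
    patch = image[r:r + th, c:c + tw].astype(np.int64)
    return int(np.abs(patch - template.astype(np.int64)).sum())


def _sad_map_binary(image01: np.ndarray, template01: np.ndarray) -> np.ndarray:
    """SAD/255 at every valid origin for {0,1} image and template.

    For binary values |a-b| = a + b - 2ab, so the map is a windowed sum of
    the image plus the template mass minus twice the cross-correlation; the
    correlation is done with an FFT and rounded back to exact integers.
    """
    th, tw = template01.shape
    ii = np.zeros((image01.shape[0] + 1, image01.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(image01, axis=0), axis=1)
    window_sum = ii[th:, tw:] - ii[:-th, tw:] - ii[th:, :-tw] + ii[:-th, :-tw]
    cross = fftconvolve(image01.astype(np.float64),
                        template01[::-1, ::-1].astype(np.float64), mode="valid")
    sad01 = window_sum - 2 * np.rint(cross).astype(np.int64) + int(template01.sum())
    return np.maximum(sad01, 0)


def _sad_map_general(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Exact SAD map by chunked sliding windows (arbitrary 8-bit values)."""
    th, tw = template.shape
    h = image.shape[0] - th + 1
    w = image.shape[1] - tw + 1
    tmpl = template.astype(np.int32)
    out = np.empty((h, w), dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(image.astype(np.int32), (th, tw))
    chunk = max(1, int(2e7 // (w * th * tw)))  # bound temporary size
    for r0 in range(0, h, chunk):
        r1 = min(h, r0 + chunk)
        out[r0:r1] = np.abs(windows[r0:r1] - tmpl).sum(axis=(2, 3))
    return out


def match_vertebra(slice2d: np.ndarray, templates: TemplateSet,
                   search_box: Optional[tuple[int, int, int, int]] = None,
                   slice_index: int = 0) -> VertebraDetection:
    """Find the (template, origin) pair minimizing SAD over the search region.

    Ties break toward the smaller template index, then raster order of the
    origin.  The search region is a half-open (r0, c0, r1, c1) box of
    allowed *origins plus template extents* (whole slice if None).
    """
    slice2d = np.asarray(slice2d)
    H, W = slice2d.shape
    if search_box is None:
        search_box = (0, 0, H, W)
    r0, c0, r1, c1 = search_box
    sub = slice2d[r0:r1, c0:c1]
    is_binary = bool(np.isin(np.unique(slice2d), (0, 255)).all())

    best = None  # (score, template_idx, row, col)
    for idx, tmpl in enumerate(templates.templates):
        th, tw = tmpl.shape
        if th > sub.shape[0] or tw > sub.shape[1]:
            continue
        if is_binary and np.isin(np.unique(tmpl), (0, 255)).all():
            smap = _sad_map_binary(sub // 255, tmpl // 255) * 255
        else:
            smap = _sad_map_general(sub, tmpl)
        flat = int(np.argmin(smap))
        rr, cc = divmod(flat, smap.shape[1])
        score = int(smap[rr, cc])
        cand = (score, idx, rr + r0, cc + c0)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise ParameterError("no template fits inside the search region")
    score, idx, rr, cc = best
    tmpl = templates.templates[idx]
    fg = np.argwhere(tmpl > 0)
    if fg.size:
        br0, bc0 = fg.min(axis=0)
        br1, bc1 = fg.max(axis=0) + 1
    else:  # all-background template: fall back to its full extent
        br0 = bc0 = 0
        br1, bc1 = tmpl.shape
    box = (rr + int(br0), cc + int(bc0), rr + int(br1), cc + int(bc1))
    return VertebraDetection(slice_index, (rr, cc), templates.ids[idx],
                             score, box)


# ---------------------------------------------------------------------------
# Vertebra / sternum erasure
# ---------------------------------------------------------------------------

def _clip_box(box: tuple[int, int, int, int], shape: tuple[int, int]):
    r0, c0, r1, c1 = box
    return (max(r0, 0), max(c0, 0), min(r1, shape[0]), min(c1, shape[1]))


def erase_vertebra_sternum(slice2d: np.ndarray, det: VertebraDetection,
                           body_centroid_y: float, margin: int = 0):
    """Zero-pad the detected vertebral box and the sternum box facing it.

    The sternum box has the same extent as the vertebra box with its center
    row reflected across ``body_centroid_y`` (vertebra posterior, sternum
    anterior on the same midline).  Both boxes are expanded by ``margin``
    and clipped to the slice.  Returns ``(slice, vertebra_box, sternum_box)``
    with the erased (clipped) boxes.
    """
    out = np.asarray(slice2d).copy()
    r0, c0, r1, c1 = det.box
    vbox = _clip_box((r0 - margin, c0 - margin, r1 + margin, c1 + margin), out.shape)
    out[vbox[0]:vbox[2], vbox[1]:vbox[3]] = 0
    center_r = (r0 + r1) / 2.0
    mirror_r = 2.0 * body_centroid_y - center_r
    half_h = (r1 - r0) / 2.0
    s_r0 = int(round(mirror_r - half_h))
    s_r1 = s_r0 + (r1 - r0)
    sbox = _clip_box((s_r0 - margin, c0 - margin, s_r1 + margin, c1 + margin), out.shape)
    out[sbox[0]:sbox[2], sbox[1]:sbox[3]] = 0
    return out, vbox, sbox


# ---------------------------------------------------------------------------
# Bed and noise removal
# ---------------------------------------------------------------------------

def remove_bed_and_noise(vol: BinaryVolume, min_size: int = 20,
                         opening_radius: int = 1, bed_band: int = 10) -> BinaryVolume:
    """Per-slice morphological cleanup: opening, small-object removal, and
    removal of components whose bounding box reaches into the posterior
    border band (the scanner bed).  Never adds foreground."""
    fg = vol.foreground()
    out = np.zeros_like(fg)
    H = fg.shape[1]
    footprint = disk(opening_radius) if opening_radius > 0 else None
    for z in range(fg.shape[0]):
        sl = fg[z]
        if not sl.any():
            continue
        if footprint is not None:
            sl = ndimage.binary_opening(sl, structure=footprint)
        labels, n = ndimage.label(sl, structure=_CROSS)
        if n == 0:
            continue
        keep = np.ones(n + 1, dtype=bool)
        keep[0] = False
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        keep &= sizes >= min_size
        if bed_band > 0:
            slices_bb = ndimage.find_objects(labels)
            for i, sl_bb in enumerate(slices_bb, start=1):
                if sl_bb is not None and sl_bb[0].stop > H - bed_band:
                    keep[i] = False
        out[z] = keep[labels]
    return BinaryVolume(np.where(out, 255, 0).astype(np.uint8), vol.spacing)


# ---------------------------------------------------------------------------
# 2D region growing and non-rib exclusion
# ---------------------------------------------------------------------------

def extract_slice_objects(slice2d: np.ndarray, slice_index: int = 0) -> list[Region2D]:
    """Raster-seeded four-connected region growing over one binary slice.

    Scans from (0, 0) in raster order; each unvisited 255 pixel seeds a
    region grown through four-connected neighbors until no pixel can be
    added.  Regions are returned in seed raster order.
    """
    arr = np.asarray(slice2d)
    fg = arr == 255
    H, W = fg.shape
    visited = np.zeros_like(fg)
    regions: list[Region2D] = []
    for r, c in np.argwhere(fg):  # argwhere yields raster order
        if visited[r, c]:
            continue
        seed = (int(r), int(c))
        pixels = set()
        queue = deque([seed])
        visited[r, c] = True
        while queue:
            y, x = queue.popleft()
            pixels.add((y, x))
            for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                if 0 <= ny < H and 0 <= nx < W and fg[ny, nx] and not visited[ny, nx]:
                    visited[ny, nx] = True
                    queue.append((ny, nx))
        regions.append(Region2D(slice_index, pixels, seed))
    return regions


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, a):
        self.parent.setdefault(a, a)
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _box_chebyshev_distance(pixels: np.ndarray, box: tuple[int, int, int, int]) -> int:
    """Minimum Chebyshev distance from any (y, x) pixel to a half-open box."""
    r0, c0, r1, c1 = box
    dy = np.maximum(np.maximum(r0 - pixels[:, 0], pixels[:, 0] - (r1 - 1)), 0)
    dx = np.maximum(np.maximum(c0 - pixels[:, 1], pixels[:, 1] - (c1 - 1)), 0)
    return int(np.maximum(dy, dx).min()) if len(pixels) else np.iinfo(np.int32).max


def filter_nonrib_objects(vol: BinaryVolume,
                          detections: Sequence[VertebraDetection],
                          contact_margin: int = 3) -> RibMask:
    """Exclude 3D bone objects not in contact with the vertebral region.

    2D four-connected regions are linked across consecutive slices by pixel
    overlap into 3D objects.  An object is kept iff, on its first slice of
    appearance, at least one pixel lies within ``contact_margin`` (Chebyshev
    distance) of that slice's vertebra box; otherwise it is zeroed
    everywhere and logged.  Slices without a detection reuse the nearest
    superior slice's detection.
    """
    fg = vol.foreground()
    nz = fg.shape[0]
    det_by_slice: dict[int, VertebraDetection] = {}
    for det in detections:
        det_by_slice[det.slice_index] = det

    # Per-slice 2D regions and region-index maps.
    slice_regions: list[list[Region2D]] = []
    region_maps = np.full(fg.shape, -1, dtype=np.int32)
    for z in range(nz):
        regions = extract_slice_objects(np.where(fg[z], 255, 0), z)
        slice_regions.append(regions)
        for i, reg in enumerate(regions):
            idx = np.array(list(reg.pixels))
            region_maps[z, idx[:, 0], idx[:, 1]] = i

    # Link regions across consecutive slices by >=1 pixel overlap.
    uf = _UnionFind()
    for z in range(nz):
        for i in range(len(slice_regions[z])):
            uf.find((z, i))
    for z in range(nz - 1):
        both = fg[z] & fg[z + 1]
        if not both.any():
            continue
        a = region_maps[z][both]
        b = region_maps[z + 1][both]
        for pa, pb in set(zip(a.tolist(), b.tolist())):
            uf.union((z, pa), (z + 1, pb))

    # Group into 3D objects and apply the first-appearance contact rule.
    objects: dict = {}
    for z in range(nz):
        for i, reg in enumerate(slice_regions[z]):
            objects.setdefault(uf.find((z, i)), []).append(reg)
    out = fg.copy()
    removed_log = []
    for obj_regions in objects.values():
        first_slice = min(r.slice_index for r in obj_regions)
        # nearest superior detection at or above the first-appearance slice
        det = None
        for z in range(first_slice, -1, -1):
            if z in det_by_slice:
                det = det_by_slice[z]
                break
        if det is None:
            raise ProcessingError(
                f"no vertebra detection available for first-appearance slice {first_slice}")
        first_pixels = np.array(
            [p for r in obj_regions if r.slice_index == first_slice for p in r.pixels])
        dist = _box_chebyshev_distance(first_pixels, det.box)
        if dist > contact_margin:
            size = sum(r.size for r in obj_regions)
            for r in obj_regions:
                idx = np.array(list(r.pixels))
                out[r.slice_index, idx[:, 0], idx[:, 1]] = False
            removed_log.append({"stage": "filter_nonrib_objects",
                                "first_slice": int(first_slice),
                                "voxels": int(size),
                                "distance": int(dist)})
    mask = BinaryVolume(np.where(out, 255, 0).astype(np.uint8), vol.spacing)
    return RibMask(mask, list(detections), removed_log)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def _body_centroid_row(win_slice: np.ndarray) -> Optional[float]:
    """Centroid row of the body: the largest connected region of non-air
    pixels in the windowed slice (excludes the detached scanner bed)."""
    body = win_slice > 0
    if not body.any():
        return None
    labels, n = ndimage.label(body, structure=_CROSS)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    rows = np.nonzero(labels == largest)[0]
    return float(rows.mean())


def build_iip_mask(win: WindowedVolume, templates: TemplateSet,
                   config: IIPConfig | None = None) -> RibMask:
    """Run the full IIP pipeline: binarize, per-slice vertebra matching and
    vertebra/sternum erasure, bed/noise cleanup, and non-rib exclusion."""
    cfg = config or IIPConfig()
    binary = binarize(win, cfg.threshold)
    nz, H, W = binary.shape
    search_box = (H // 2, 0, H, W) if cfg.search == "posterior" else None

    raw_dets: list[Optional[VertebraDetection]] = []
    for z in range(nz):
        sl = binary.voxels[z]
        if not (sl > 0).any():
            raw_dets.append(None)
            continue
        det = match_vertebra(sl, templates, search_box, slice_index=z)
        if cfg.sad_ceiling is not None and det.score > cfg.sad_ceiling:
            det = None
        raw_dets.append(det)

    # Slices without a reliable match reuse the nearest superior detection.
    detections: list[VertebraDetection] = []
    erased = binary.voxels.copy()
    removed_log = []
    last: Optional[VertebraDetection] = None
    for z in range(nz):
        det = raw_dets[z]
        if det is None and last is not None:
            det = VertebraDetection(z, last.top_left, last.template_id,
                                    last.score, last.box)
        if det is None:
            continue
        last = det
        detections.append(det)
        centroid = _body_centroid_row(win.voxels[z])
        if centroid is None:
            centroid = (det.box[0] + det.box[2]) / 2.0
        erased[z], vbox, sbox = erase_vertebra_sternum(
            erased[z], det, centroid, cfg.erase_margin)
        removed_log.append({"stage": "erase_vertebra_sternum", "slice": z,
                            "vertebra_box": [int(v) for v in vbox],
                            "sternum_box": [int(v) for v in sbox]})

    if not detections:
        msg = "no vertebra detected anywhere in the volume"
        if cfg.on_no_vertebra == "raise":
            raise ProcessingError(msg)
        import warnings
        warnings.warn(msg, stacklevel=2)
        empty = BinaryVolume(np.zeros_like(binary.voxels), binary.spacing)
        return RibMask(empty, [], [{"stage": "build_iip_mask", "warning": msg}])

    cleaned = remove_bed_and_noise(BinaryVolume(erased, binary.spacing),
                                   cfg.min_size, cfg.opening_radius, cfg.bed_band)
    mask = filter_nonrib_objects(cleaned, detections, cfg.contact_margin)
    mask.removed = removed_log + mask.removed
    return mask
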