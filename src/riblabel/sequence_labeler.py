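"""Ordinal rib sequence labeling by 3D six-connected region growing.

Given a ribs-only binary volume, every rib is objectified as a maximal
six-connected voxel cluster (neighbors along the x, y and z axes only),
seeded in raster-scan order starting from the first (most superior) slice.
Because ribs slope inferiorly, the order in which clusters first appear
from the top of the stack equals their anatomical ordinal, so the 24
clusters of a full rib cage are paired into rib pairs 1-12 by sorting each
body side by first-appearance slice.  Display annotations carry the
ordinal of each left-side rib only, matching how radiologists read the
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .errors import ParameterError
from .iip_mask import RibMask
from .volume_io import BinaryVolume, LabelVolume


@dataclass
class Cluster3D:
    """One six-connected foreground component (one rib, ideally)."""

    id: int                       # ordinal by discovery
    voxels: np.ndarray            # (n, 3) array of (z, y, x)
    seed: tuple[int, int, int]    # first voxel found (raster order)
    side: Optional[str] = None    # 'left' | 'right'
    pair_ordinal: Optional[int] = None

    @property
    def first_slice(self) -> int:
        return int(self.voxels[:, 0].min())

    @property
    def size(self) -> int:
        return len(self.voxels)

    @property
    def centroid(self) -> tuple[float, float, float]:
        z, y, x = self.voxels.mean(axis=0)
        return (float(z), float(y), float(x))


@dataclass
class RibLabelReport:
    """Pairing of clusters into rib pairs plus left-side display annotations."""

    pairs: list = field(default_factory=list)        # (ordinal, left_id, right_id)
    unpaired: list = field(default_factory=list)     # cluster ids with no partner
    annotations: list = field(default_factory=list)  # (z, y, x, ordinal), left side
    warnings: list = field(default_factory=list)
    case_id: str = ""

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "pairs": [{"ordinal": o, "left_cluster": l, "right_cluster": r}
                      for o, l, r in self.pairs],
            "unpaired": list(self.unpaired),
            "annotations": [{"z": z, "y": y, "x": x, "ordinal": o}
                            for z, y, x, o in self.annotations],
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RibLabelReport":
        return cls(
            pairs=[(p["ordinal"], p["left_cluster"], p["right_cluster"])
                   for p in data.get("pairs", [])],
            unpaired=list(data.get("unpaired", [])),
            annotations=[(a["z"], a["y"], a["x"], a["ordinal"])
                         for a in data.get("annotations", [])],
            warnings=list(data.get("warnings", [])),
            case_id=data.get("case_id", ""),
        )


@dataclass
class LabelConfig:
    min_cluster_size: int = 30   # noise guard; 0 grows every foreground voxel
    max_pairs: int = 12          # anatomical rib pair count
    midline_x: Optional[float] = None  # override laterality midline column

    @classmethod
    def from_file(cls, path: str | Path) -> "LabelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _as_binary(mask: Union[RibMask, BinaryVolume]) -> BinaryVolume:
    return mask.volume if isinstance(mask, RibMask) else mask


# ---------------------------------------------------------------------------
# 3D region growing
# ---------------------------------------------------------------------------

def grow_3d(vol: Union[BinaryVolume, np.ndarray], seed: tuple[int, int, int],
            visited: Optional[np.ndarray] = None) -> Cluster3D:
    """Grow the maximal six-connected foreground component containing ``seed``.

    A voxel joins the cluster iff its value is 255 and it is face-adjacent
    (x, y or z neighbor) to a voxel already in the cluster.  Membership is
    a set and therefore independent of traversal order.  ``visited`` (a
    boolean array of the volume's shape) is updated in place.
    """
    fg = vol.foreground() if isinstance(vol, BinaryVolume) else np.asarray(vol) == 255
    z, y, x = seed
    if not fg[z, y, x]:
        raise ParameterError(f"seed {seed} is not a foreground voxel")
    if visited is None:
        visited = np.zeros(fg.shape, dtype=bool)
    if visited[z, y, x]:
        raise ParameterError(f"seed {seed} was already visited")

    # Vectorized wavefront flood fill: expand all six face neighbors of the
    # current frontier at once until no new voxel is reached.
    member = np.zeros(fg.shape, dtype=bool)
    member[z, y, x] = True
    memberf = member.ravel()
    fgf = fg.ravel()
    frontier = np.array([[z, y, x]], dtype=np.intp)
    shape = np.array(fg.shape)
    offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.intp)
    while len(frontier):
        cand = (frontier[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        ok = np.all((cand >= 0) & (cand < shape), axis=1)
        cand = cand[ok]
        flat = np.ravel_multi_index((cand[:, 0], cand[:, 1], cand[:, 2]), fg.shape)
        flat = np.unique(flat)
        flat = flat[fgf[flat] & ~memberf[flat]]
        if not len(flat):
            break
        memberf[flat] = True
        frontier = np.stack(np.unravel_index(flat, fg.shape), axis=1)
    voxels = np.argwhere(member)
    visited |= member
    return Cluster3D(id=0, voxels=voxels, seed=(int(z), int(y), int(x)))


def label_clusters(mask: Union[RibMask, BinaryVolume],
                   min_cluster_size: int = 30) -> tuple[LabelVolume, list[Cluster3D]]:
    """Objectify every six-connected component, scanning from the first slice.

    Seeds are taken in raster order (z, then y, then x); clusters smaller
    than ``min_cluster_size`` voxels are dropped as noise.  Surviving
    clusters get ids 1, 2, ... in discovery order — ascending first slice,
    ties broken by the raster order of their seeds.
    """
    vol = _as_binary(mask)
    fg = vol.foreground()
    visited = np.zeros(fg.shape, dtype=bool)
    labels = np.zeros(fg.shape, dtype=np.int32)
    clusters: list[Cluster3D] = []
    flat_fg = np.flatnonzero(fg.ravel())
    next_id = 1
    for flat in flat_fg:
        idx = np.unravel_index(flat, fg.shape)
        if visited[idx]:
            continue
        cluster = grow_3d(vol, (int(idx[0]), int(idx[1]), int(idx[2])), visited)
        if cluster.size < min_cluster_size:
            continue
        cluster.id = next_id
        labels[cluster.voxels[:, 0], cluster.voxels[:, 1], cluster.voxels[:, 2]] = next_id
        clusters.append(cluster)
        next_id += 1
    return LabelVolume(labels, vol.spacing, len(clusters)), clusters


# ---------------------------------------------------------------------------
# Laterality and pairing
# ---------------------------------------------------------------------------

def assign_side(cluster: Cluster3D, midline_x: float) -> str:
    """Patient side of a cluster: centroid columns beyond the midline are
    'left' (patient left appears on the image's right); ties go right."""
    side = "left" if cluster.centroid[2] > midline_x else "right"
    cluster.side = side
    return side


def pair_ribs(clusters: Sequence[Cluster3D], max_pairs: int = 12) -> RibLabelReport:
    """Pair left and right clusters into ordinal rib pairs.

    Within each side, clusters sorted by (first slice, seed raster order)
    receive side-ordinals 1, 2, ...; pair i joins the i-th left with the
    i-th right cluster.  Surplus clusters on the longer side are reported
    as unpaired; more than ``max_pairs`` pairs flags the case.
    """
    report = RibLabelReport()
    sides = {"left": [], "right": []}
    for c in clusters:
        if c.side not in sides:
            raise ParameterError(f"cluster {c.id} has no side assigned")
        sides[c.side].append(c)
    for lst in sides.values():
        lst.sort(key=lambda c: (c.first_slice, c.seed))
    n_pairs = min(len(sides["left"]), len(sides["right"]))
    for i in range(n_pairs):
        left, right = sides["left"][i], sides["right"][i]
        ordinal = i + 1
        left.pair_ordinal = right.pair_ordinal = ordinal
        report.pairs.append((ordinal, left.id, right.id))
        if ordinal > max_pairs:
            report.warnings.append(
                f"pair {ordinal} exceeds the {max_pairs} anatomical rib pairs; "
                "a non-rib object was likely labeled")
    for side_name, lst in sides.items():
        for c in lst[n_pairs:]:
            report.unpaired.append(c.id)
            report.warnings.append(
                f"unpaired {side_name} cluster {c.id} (first slice {c.first_slice})")
    if len(sides["left"]) != len(sides["right"]):
        report.warnings.append(
            f"left/right cluster count asymmetry: {len(sides['left'])} vs "
            f"{len(sides['right'])}")
    return report


def label_sequence(mask: Union[RibMask, BinaryVolume],
                   config: LabelConfig | None = None,
                   case_id: str = "") -> tuple[LabelVolume, RibLabelReport]:
    """Full sequence labeling: cluster, side, pair, re-code and annotate.

    The returned LabelVolume re-codes paired clusters so that for P pairs
    the left rib of pair i has label i and the right rib label P + i (the
    set {1..2P} exactly; 12 + i for a full rib cage).  Unpaired clusters
    stay in the report but are not re-coded.  Annotations mark each left
    rib's lateral-most voxel on its first slice with the pair ordinal.
    """
    cfg = config or LabelConfig()
    vol = _as_binary(mask)
    _, clusters = label_clusters(mask, cfg.min_cluster_size)

    if cfg.midline_x is not None:
        midline = float(cfg.midline_x)
    elif isinstance(mask, RibMask) and mask.detections:
        midline = float(np.mean([(d.box[1] + d.box[3]) / 2.0 for d in mask.detections]))
    else:
        midline = (vol.shape[2] - 1) / 2.0
    for c in clusters:
        assign_side(c, midline)

    report = pair_ribs(clusters, cfg.max_pairs)
    report.case_id = case_id

    n_pairs = len(report.pairs)
    by_id = {c.id: c for c in clusters}
    recoded = np.zeros(vol.shape, dtype=np.int32)
    for ordinal, left_id, right_id in report.pairs:
        left, right = by_id[left_id], by_id[right_id]
        recoded[left.voxels[:, 0], left.voxels[:, 1], left.voxels[:, 2]] = ordinal
        recoded[right.voxels[:, 0], right.voxels[:, 1], right.voxels[:, 2]] = n_pairs + ordinal
        # annotation: lateral-most (largest x) voxel on the left rib's first slice
        first = left.voxels[left.voxels[:, 0] == left.first_slice]
        pos = first[np.argmax(first[:, 2])]
        report.annotations.append((int(pos[0]), int(pos[1]), int(pos[2]), ordinal))
    label_vol = LabelVolume(recoded, vol.spacing, 2 * n_pairs if n_pairs else 0)
    return label_vol, report
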