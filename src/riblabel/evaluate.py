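"""Case-level labeling success, cohort success rates and error taxonomy.

A case is successful when every ground-truth rib is matched by exactly one
predicted cluster carrying the correct ordinal and side, and no predicted
cluster lands on a non-rib structure.  Failures are classified into the
three observed error modes:

* ``overlapped_pair`` — one predicted cluster covers two adjacent truth
  ribs (converging true ribs merged into a single label);
* ``missed_rib`` — a truth rib has no predicted cluster that correctly
  labels it (typically a small 12th rib lost during masking);
* ``nonrib_labeled`` — a predicted cluster mostly overlaps a non-rib bone
  (clavicle, scapula) or nothing at all.

The cohort success rate is the fraction of cases with all rib pairs
labeled in the correct sequence, reported in percent with a normal-
approximation 95% confidence interval clipped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .errors import ParameterError
from .phantom import PhantomTruth
from .sequence_labeler import RibLabelReport
from .volume_io import LabelVolume

# A predicted cluster must cover a region with at least this fraction of
# its own voxels to count as matching it.
MATCH_OVERLAP_FRACTION = 0.5


@dataclass
class CaseResult:
    case_id: str
    success: bool
    errors: list = field(default_factory=list)
    per_pair: dict = field(default_factory=dict)  # ordinal -> correctly labeled
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.success == (not self.errors)

    def to_dict(self) -> dict:
        return {"case_id": self.case_id, "success": self.success,
                "errors": list(self.errors),
                "per_pair": {str(k): v for k, v in self.per_pair.items()},
                "notes": list(self.notes)}


@dataclass
class CohortResult:
    n_cases: int
    n_success: int
    rate: float            # percent
    ci95: tuple[float, float]  # percent, clipped to [0, 100]

    def to_dict(self) -> dict:
        return {"n_cases": self.n_cases, "n_success": self.n_success,
                "rate": self.rate, "ci95": list(self.ci95)}


def _truth_regions(truth: Union[PhantomTruth, LabelVolume, np.ndarray]):
    """Return (rib label array, rib_info, structure-id array, names)."""
    if isinstance(truth, PhantomTruth):
        rib = truth.rib_labels
        info = dict(truth.rib_info)
        struct = np.zeros(rib.shape, dtype=np.int32)
        names = {}
        for i, (name, m) in enumerate(truth.structures.items(), start=1):
            struct[m] = i
            names[i] = name
        return rib, info, struct, names
    arr = truth.voxels if isinstance(truth, LabelVolume) else np.asarray(truth)
    labels = np.unique(arr)
    labels = labels[labels > 0]
    n_pairs = int(labels.max()) // 2 if labels.size else 0
    info = {}
    for lbl in labels:
        lbl = int(lbl)
        if lbl <= n_pairs:
            info[lbl] = ("left", lbl)
        else:
            info[lbl] = ("right", lbl - n_pairs)
    return arr, info, np.zeros(arr.shape, dtype=np.int32), {}


def case_success(pred: LabelVolume, report: RibLabelReport,
                 truth: Union[PhantomTruth, LabelVolume, np.ndarray],
                 case_id: str = "") -> CaseResult:
    """Judge one case's sequence labeling against ground truth.

    Each predicted cluster is matched to the truth region (rib or named
    structure) holding the plurality of its voxels; the match must cover at
    least half the cluster.  A truth rib whose ordinal+side is not claimed
    by a correctly matched cluster counts as missed.
    """
    pred_arr = pred.voxels
    rib_arr, rib_info, struct_arr, struct_names = _truth_regions(truth)
    if pred_arr.shape != rib_arr.shape:
        raise ParameterError(
            f"geometry mismatch: prediction {pred_arr.shape} vs truth {rib_arr.shape}")

    n_pairs = len(report.pairs)
    errors: set[str] = set()
    notes: list[str] = []
    truth_sizes = {lbl: int(np.count_nonzero(rib_arr == lbl)) for lbl in rib_info}
    matched_rib_by: dict[int, list[int]] = {lbl: [] for lbl in rib_info}
    correct_ordinals: dict[tuple[str, int], bool] = {
        (side, o): False for (side, o) in rib_info.values()}

    for lbl in range(1, pred.label_count + 1):
        sel = pred_arr == lbl
        size = int(np.count_nonzero(sel))
        if size == 0:
            continue
        side = "left" if lbl <= n_pairs else "right"
        ordinal = lbl if lbl <= n_pairs else lbl - n_pairs
        rib_over = np.bincount(rib_arr[sel].ravel())
        struct_over = np.bincount(struct_arr[sel].ravel())
        best_rib = int(rib_over[1:].argmax()) + 1 if rib_over.size > 1 else 0
        best_rib_count = int(rib_over[best_rib]) if best_rib else 0
        best_struct = int(struct_over[1:].argmax()) + 1 if struct_over.size > 1 else 0
        best_struct_count = int(struct_over[best_struct]) if best_struct else 0

        covered = [t for t in rib_info
                   if t < rib_over.size
                   and int(rib_over[t]) >= 0.5 * truth_sizes[t]]
        if len(covered) >= 2:
            errors.add("overlapped_pair")
            notes.append(f"cluster {lbl} covers truth ribs {sorted(covered)}")

        if best_rib_count < MATCH_OVERLAP_FRACTION * size or best_rib_count == 0:
            errors.add("nonrib_labeled")
            what = struct_names.get(best_struct, "background") \
                if best_struct_count >= best_rib_count else "background"
            notes.append(f"cluster {lbl} ({side} ordinal {ordinal}) mostly "
                         f"overlaps {what}")
            continue
        t_side, t_ord = rib_info[best_rib]
        matched_rib_by[best_rib].append(lbl)
        if (t_side, t_ord) == (side, ordinal) and len(covered) <= 1:
            correct_ordinals[(side, ordinal)] = True
        else:
            notes.append(f"cluster {lbl} labeled ({side}, {ordinal}) but matches "
                         f"truth rib ({t_side}, {t_ord})")

    for lbl, (side, ordinal) in rib_info.items():
        if not matched_rib_by[lbl] or not correct_ordinals[(side, ordinal)]:
            errors.add("missed_rib")
            notes.append(f"truth rib ({side}, {ordinal}) not correctly labeled")

    per_pair = {o: correct_ordinals.get(("left", o), False)
                and correct_ordinals.get(("right", o), False)
                for o in sorted({o for _, o in rib_info.values()})}
    success = not errors
    return CaseResult(case_id, success, sorted(errors), per_pair, notes)


def _cohort(n_success: int, n_cases: int) -> CohortResult:
    if n_cases < 1:
        raise ParameterError("cohort requires at least one case")
    p = n_success / n_cases
    rate = 100.0 * p
    half = 1.959963984540054 * np.sqrt(p * (1 - p) / n_cases) * 100.0
    lo = max(0.0, rate - half)
    hi = min(100.0, rate + half)
    return CohortResult(n_cases, n_success, rate, (lo, hi))


def success_rate(results: Sequence[CaseResult]) -> CohortResult:
    """Aggregate case results: percent of fully successful cases with a
    normal-approximation 95% CI clipped to [0, 100]."""
    if not results:
        raise ParameterError("success_rate needs at least one CaseResult")
    n_success = sum(1 for r in results if r.success)
    return _cohort(n_success, len(results))


def cohort_from_counts(n_success: int, n_cases: int) -> CohortResult:
    """Cohort summary directly from success/total counts."""
    if not 0 <= n_success <= n_cases:
        raise ParameterError("need 0 <= n_success <= n_cases")
    return _cohort(n_success, n_cases)
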