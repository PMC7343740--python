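"""The three MTV/TLG measurement workflows.

* **Workflow A** — user-defined lesion selection: one click per lesion, each
  click refined to a robust local maximum and segmented by the four
  threshold methods (plus MV2/MV3 consensus); per-method lesion masks are
  unioned into total MTV and TLG.
* **Workflow B** — fully automated preselection of all FDG-avid structures
  (SUV >= 4.0, volume >= 3 ml); the observer only clears non-tumor regions
  or restricts the axial field of view.
* **Workflow C** — Workflow B's preselection modified by an edit script:
  adding missed lesions (adaptive A50%P segmentation from a seed, or a
  manual mask) and erasing physiological uptake (C1), optionally followed
  by a second edit pass representing the physician check (C2).

Interactive editing is replaced by declarative, replayable
:class:`EditScript` objects so every analysis is reproducible.  Totals are
always computed on the *union* of the current masks, so overlapping lesions
are never double-counted and MTV is invariant to how a voxel set is
partitioned into lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .image import SeedClick, SuvVolume, VoiMask, crop_axial_range
from .metrics import tlg as _tlg
from .segmentation import (
    MethodId,
    Region,
    SegmentationError,
    majority_vote,
    preselect_regions,
    robust_local_max,
    segment_a50p,
    segment_fixed_threshold,
    segment_pct_max,
)

__all__ = [
    "RatingValue",
    "QualityRating",
    "LesionRecord",
    "SegmentationResult",
    "ClearRegion",
    "CropAxial",
    "AddLesionA50P",
    "AddLesionManual",
    "Erase",
    "EditScript",
    "run_workflow_a",
    "run_workflow_b",
    "run_workflow_c",
    "apply_physician_check",
    "success_rate",
]


class RatingValue(str, Enum):
    """Observer rating of a generated VOI.

    FAILED: unrealistic or incomplete; POOR: includes physiological uptake
    or much background, heavy editing needed; ACCEPTABLE: minimal editing
    needed; GOOD: matches what the observer considers tumor.
    """

    FAILED = "failed"
    POOR = "poor"
    ACCEPTABLE = "acceptable"
    GOOD = "good"


@dataclass(frozen=True)
class QualityRating:
    value: RatingValue
    observer_id: str = ""
    target: str = ""  # lesion or scan identifier


def success_rate(ratings) -> float:
    """Fraction of ratings that are ACCEPTABLE or GOOD."""
    values = [r.value if isinstance(r, QualityRating) else RatingValue(r) for r in ratings]
    if not values:
        raise ValueError("success_rate requires at least one rating")
    ok = sum(v in (RatingValue.ACCEPTABLE, RatingValue.GOOD) for v in values)
    return ok / len(values)


# ---------------------------------------------------------------------------
# Results


@dataclass
class LesionRecord:
    """One per-click segmentation outcome; failures are retained, not dropped."""

    click: SeedClick
    refined_seed: tuple[int, int, int] | None
    mask: VoiMask | None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.mask is None


@dataclass
class SegmentationResult:
    """Total MTV/TLG for one (patient, observer, workflow, method) cell."""

    patient_id: str
    observer_id: str
    workflow: str  # "A", "B", "C1", "C2"
    method: str
    lesions: list[LesionRecord] = field(default_factory=list)
    region_masks: dict[int, VoiMask] = field(default_factory=dict)
    extra_masks: list[VoiMask] = field(default_factory=list)
    union_mask: VoiMask | None = None
    mtv_ml: float = 0.0
    tlg: float = 0.0
    ratings: list[QualityRating] = field(default_factory=list)

    def all_masks(self) -> list[VoiMask]:
        masks = [rec.mask for rec in self.lesions if rec.mask is not None]
        masks.extend(self.region_masks.values())
        masks.extend(self.extra_masks)
        return masks


def _finalize(volume: SuvVolume, result: SegmentationResult) -> SegmentationResult:
    masks = result.all_masks()
    if masks:
        union = np.zeros(volume.shape, dtype=bool)
        for m in masks:
            m.check_aligned(volume)
            union |= m.values
        result.union_mask = VoiMask.from_volume(
            volume, union, method=result.method, observer=result.observer_id
        )
        result.mtv_ml = result.union_mask.volume_ml
        result.tlg = _tlg(volume, result.union_mask) if union.any() else 0.0
    else:
        result.union_mask = VoiMask.from_volume(
            volume, np.zeros(volume.shape, dtype=bool), method=result.method
        )
        result.mtv_ml = 0.0
        result.tlg = 0.0
    return result


# ---------------------------------------------------------------------------
# Edit scripts


@dataclass(frozen=True)
class ClearRegion:
    """Remove one preselected region (single-click clearing)."""

    region_id: int


@dataclass(frozen=True)
class CropAxial:
    """Restrict the analyzed field of view to slices [z_lo, z_hi)."""

    z_lo: int
    z_hi: int


@dataclass(frozen=True)
class AddLesionA50P:
    """Add a missed lesion by adaptive A50%P segmentation from a seed click."""

    seed: tuple[int, int, int]


@dataclass
class AddLesionManual:
    """Add a missed lesion as a manually drawn mask."""

    mask: VoiMask


@dataclass
class Erase:
    """Remove the given voxels from every current mask (eraser tool)."""

    mask: VoiMask


@dataclass
class EditScript:
    """An ordered, replayable list of edit operations."""

    ops: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.ops)

    def __len__(self) -> int:
        return len(self.ops)


_B_OPS = (ClearRegion, CropAxial)
_C_OPS = (ClearRegion, CropAxial, AddLesionA50P, AddLesionManual, Erase)


def _apply_edits(
    volume: SuvVolume,
    region_masks: dict[int, VoiMask],
    extra_masks: list[VoiMask],
    edits: EditScript | None,
    allowed: tuple,
    connectivity: int = 26,
) -> tuple[dict[int, VoiMask], list[VoiMask]]:
    region_masks = dict(region_masks)
    extra_masks = list(extra_masks)
    for op in edits or []:
        if not isinstance(op, allowed):
            raise TypeError(
                f"operation {type(op).__name__} not allowed in this workflow"
            )
        if isinstance(op, ClearRegion):
            if op.region_id not in region_masks:
                raise KeyError(
                    f"cannot clear region {op.region_id}: no such preselected region"
                )
            del region_masks[op.region_id]
        elif isinstance(op, CropAxial):
            region_masks = {
                rid: crop_axial_range(m, op.z_lo, op.z_hi)
                for rid, m in region_masks.items()
            }
            region_masks = {r: m for r, m in region_masks.items() if m.voxel_count}
            extra_masks = [
                m
                for m in (crop_axial_range(m, op.z_lo, op.z_hi) for m in extra_masks)
                if m.voxel_count
            ]
        elif isinstance(op, AddLesionA50P):
            seed = robust_local_max(volume, op.seed, connectivity=connectivity)
            extra_masks.append(segment_a50p(volume, seed, connectivity=connectivity))
        elif isinstance(op, AddLesionManual):
            op.mask.check_aligned(volume)
            extra_masks.append(op.mask)
        elif isinstance(op, Erase):
            op.mask.check_aligned(volume)
            erase = op.mask.values
            region_masks = {
                rid: VoiMask.from_volume(volume, m.values & ~erase,
                                         method=m.method, observer=m.observer)
                for rid, m in region_masks.items()
            }
            region_masks = {r: m for r, m in region_masks.items() if m.voxel_count}
            extra_masks = [
                VoiMask.from_volume(volume, m.values & ~erase,
                                    method=m.method, observer=m.observer)
                for m in extra_masks
            ]
            extra_masks = [m for m in extra_masks if m.voxel_count]
    return region_masks, extra_masks


# ---------------------------------------------------------------------------
# Workflow A


def run_workflow_a(
    volume: SuvVolume,
    clicks: list[SeedClick],
    methods: list[MethodId] | None = None,
    connectivity: int = 26,
    patient_id: str = "",
    observer_id: str = "",
) -> list[SegmentationResult]:
    """Individual lesion selection with semi-automated segmentation.

    Each click is refined by :func:`robust_local_max`; the four base methods
    are segmented from the refined seed; MV2/MV3 are voted per lesion from
    the four base masks.  One result per requested method, with totals over
    the union of that method's lesion masks.  A click that fails for a
    method (e.g. lesion SUV below a fixed threshold, or a click in
    background) yields a per-lesion failure record rather than an abort.
    """
    if not clicks:
        raise ValueError("workflow A requires at least one click")
    methods = [MethodId(m) for m in (methods or list(MethodId))]
    want_mv = MethodId.MV2 in methods or MethodId.MV3 in methods
    # Consensus needs all four base masks; otherwise only compute what was asked.
    base = MethodId.base_methods() if want_mv else tuple(
        m for m in MethodId.base_methods() if m in methods
    )
    per_method: dict[MethodId, list[LesionRecord]] = {m: [] for m in list(MethodId)}

    for click in clicks:
        click.validate(volume)
        try:
            seed = robust_local_max(volume, click, connectivity=connectivity)
        except SegmentationError as exc:
            for m in list(MethodId):
                per_method[m].append(LesionRecord(click, None, None, str(exc)))
            continue
        base_masks: dict[MethodId, VoiMask | None] = {}
        for m in base:
            try:
                if m is MethodId.FORTYONE_MAX:
                    mask = segment_pct_max(volume, seed, connectivity=connectivity)
                elif m is MethodId.A50P:
                    mask = segment_a50p(volume, seed, connectivity=connectivity)
                elif m is MethodId.SUV25:
                    mask = segment_fixed_threshold(volume, seed, 2.5, connectivity)
                else:
                    mask = segment_fixed_threshold(volume, seed, 4.0, connectivity)
                base_masks[m] = mask
                per_method[m].append(LesionRecord(click, seed, mask))
            except SegmentationError as exc:
                base_masks[m] = None
                per_method[m].append(LesionRecord(click, seed, None, str(exc)))
        if want_mv:
            # Consensus per lesion over the four base masks; a failed base
            # method contributes an empty vote.
            votes = [
                m if m is not None
                else VoiMask.from_volume(volume, np.zeros(volume.shape, dtype=bool))
                for m in base_masks.values()
            ]
            for k, mid in ((2, MethodId.MV2), (3, MethodId.MV3)):
                mv = majority_vote(votes, k)
                if mv.voxel_count:
                    per_method[mid].append(LesionRecord(click, seed, mv))
                else:
                    per_method[mid].append(
                        LesionRecord(click, seed, None, f"empty {mid.value} consensus")
                    )

    results = []
    for m in methods:
        res = SegmentationResult(
            patient_id=patient_id,
            observer_id=observer_id,
            workflow="A",
            method=m.value,
            lesions=per_method[m],
        )
        results.append(_finalize(volume, res))
    return results


# ---------------------------------------------------------------------------
# Workflow B


def run_workflow_b(
    volume: SuvVolume,
    edits: EditScript | None = None,
    suv_min: float = 4.0,
    vol_min_ml: float = 3.0,
    connectivity: int = 26,
    patient_id: str = "",
    observer_id: str = "",
    regions: list[Region] | None = None,
) -> SegmentationResult:
    """Automated preselection followed by clearing / axial cropping.

    ``regions`` may carry a precomputed preselection (identical for every
    observer by construction); otherwise it is computed here.  Only
    :class:`ClearRegion` and :class:`CropAxial` operations are allowed.
    """
    if regions is None:
        regions = preselect_regions(
            volume, suv_min, vol_min_ml, connectivity, compute_peak=False
        )
    region_masks = {r.region_id: r.mask for r in regions}
    region_masks, _ = _apply_edits(volume, region_masks, [], edits, _B_OPS)
    res = SegmentationResult(
        patient_id=patient_id,
        observer_id=observer_id,
        workflow="B",
        method="preselect",
        region_masks=region_masks,
    )
    return _finalize(volume, res)


# ---------------------------------------------------------------------------
# Workflow C


def run_workflow_c(
    volume: SuvVolume,
    b_result: SegmentationResult,
    edits: EditScript | None = None,
    connectivity: int = 26,
) -> SegmentationResult:
    """Manual modification of the Workflow B preselection (C1).

    Starts from the regions surviving ``b_result``'s edits and applies adds
    (A50%P from a seed, or manual masks), erasures, clears and crops in
    order.  An empty edit script reproduces the B result exactly.
    """
    region_masks, extra = _apply_edits(
        volume,
        b_result.region_masks,
        b_result.extra_masks,
        edits,
        _C_OPS,
        connectivity,
    )
    res = SegmentationResult(
        patient_id=b_result.patient_id,
        observer_id=b_result.observer_id,
        workflow="C1",
        method="final",
        region_masks=region_masks,
        extra_masks=extra,
    )
    return _finalize(volume, res)


def apply_physician_check(
    volume: SuvVolume,
    c1_result: SegmentationResult,
    edits: EditScript | None = None,
    connectivity: int = 26,
) -> SegmentationResult:
    """Second edit pass (nuclear-medicine physician check) producing C2."""
    region_masks, extra = _apply_edits(
        volume,
        c1_result.region_masks,
        c1_result.extra_masks,
        edits,
        _C_OPS,
        connectivity,
    )
    res = SegmentationResult(
        patient_id=c1_result.patient_id,
        observer_id=c1_result.observer_id,
        workflow="C2",
        method="final",
        region_masks=region_masks,
        extra_masks=extra,
    )
    return _finalize(volume, res)
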