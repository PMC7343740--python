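"""Digital PET phantoms with known ground truth, and stochastic observers.

The phantom generator emulates a body-like SUV volume: a low uniform
background, focal lesions (uniform ellipsoids, core+rim heterogeneous
lesions, and two-lobe "dumbbell" lesions joined by a low-uptake bridge) and
physiological-uptake structures (brain, bladder and liver analogues) that
the automated preselection will pick up alongside tumor.  Additive Gaussian
noise (truncated at 0) stands in for image noise.

The observer model turns ground truth into workflow inputs the way a human
would, with controllable error sources: isotropic click jitter (truncated to
the lesion interior), a volume-dependent probability of missing a lesion,
and per-region misclassification probabilities (keeping a physiological
region as tumor / clearing a tumor region as physiological).  A zero-jitter,
zero-error model reproduces the ground-truth decisions exactly.

``run_reliability_experiment`` crosses phantoms x observers x workflows x
methods and feeds the resulting measurement table to the reliability
statistics, so the full interobserver study design runs end-to-end with no
external data.  One master seed deterministically spawns per-patient and
per-observer child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .image import SeedClick, SuvVolume, VoiMask
from .segmentation import (
    MethodId,
    Region,
    _lexicographic_argmax,
    preselect_regions,
)
from .workflows import (
    AddLesionA50P,
    ClearRegion,
    EditScript,
    run_workflow_a,
    run_workflow_b,
    run_workflow_c,
)
from .reliability import format_report, reliability_report

__all__ = [
    "LesionSpec",
    "DumbbellSpec",
    "OrganSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomError",
    "ObserverModel",
    "ObserverActions",
    "StudyConfig",
    "ExperimentResult",
    "generate_phantom",
    "simulate_observer",
    "sample_phantom_spec",
    "run_reliability_experiment",
]


class PhantomError(ValueError):
    """Invalid phantom specification (structure outside grid or overlapping)."""


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal lesion; with ``rim_suv`` set it becomes a two-level
    core+rim heterogeneous lesion (core semi-axes = core_fraction * radii)."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv: float
    rim_suv: float | None = None
    core_fraction: float = 0.6


@dataclass(frozen=True)
class DumbbellSpec:
    """Two uptake lobes joined by a thin low-uptake bridge.

    The bridge keeps the lesion a single connected structure while its SUV
    is low enough that a region grown at 70 % of a click in the cooler lobe
    cannot cross it — the mechanism by which clicks in different parts of a
    heterogeneous lesion miss the lesion SUVmax.
    """

    center1_mm: tuple[float, float, float]
    center2_mm: tuple[float, float, float]
    radius1_mm: float
    radius2_mm: float
    suv1: float
    suv2: float
    bridge_suv: float = 4.5
    bridge_radius_mm: float = 4.0


@dataclass(frozen=True)
class OrganSpec:
    """A physiological-uptake structure (brain/bladder/liver analogue)."""

    name: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv: float


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 0.5
    noise_sd: float = 0.1
    lesions: tuple = ()
    organs: tuple = ()
    seed: int = 0


@dataclass
class PhantomTruth:
    """Noise-free ground-truth masks of a generated phantom."""

    lesion_masks: list[VoiMask]
    organ_masks: dict[str, VoiMask]

    def lesion_union(self) -> np.ndarray:
        out = np.zeros(self.lesion_masks[0].shape, dtype=bool) if self.lesion_masks \
            else np.zeros((1, 1, 1), dtype=bool)
        for m in self.lesion_masks:
            out |= m.values
        return out

    def organ_union(self) -> np.ndarray:
        masks = list(self.organ_masks.values())
        out = np.zeros(masks[0].shape, dtype=bool) if masks \
            else np.zeros((1, 1, 1), dtype=bool)
        for m in masks:
            out |= m.values
        return out


# ---------------------------------------------------------------------------
# Phantom generation


def _voxel_centers(shape, spacing):
    axes = [np.arange(n) * d for n, d in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_mask(grids, center, radii) -> np.ndarray:
    gx, gy, gz = grids
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2 + ((gz - cz) / rz) ** 2 <= 1.0


def _segment_distance(grids, p1, p2) -> np.ndarray:
    """Distance from every voxel center to the segment p1-p2 (mm)."""
    gx, gy, gz = np.broadcast_arrays(*grids)
    p = np.stack([gx, gy, gz], axis=-1).astype(np.float64)
    a = np.asarray(p1, dtype=np.float64)
    d = np.asarray(p2, dtype=np.float64) - a
    L2 = float(d @ d)
    t = np.clip(((p - a) @ d) / L2, 0.0, 1.0) if L2 > 0 else np.zeros(p.shape[:-1])
    closest = a + t[..., None] * d
    return np.linalg.norm(p - closest, axis=-1)


def _check_inside(extent, center, radius_vec) -> None:
    for c, r, e in zip(center, np.broadcast_to(radius_vec, (3,)), extent):
        if c - r < 0 or c + r > e:
            raise PhantomError(
                f"structure at {tuple(center)} (extent {tuple(np.atleast_1d(radius_vec))}) "
                f"lies partly outside the grid (extent {tuple(extent)})"
            )


def _paint_lesion(spec, grids, extent):
    """Return (mask, list of (submask, suv)) for one lesion spec."""
    if isinstance(spec, LesionSpec):
        _check_inside(extent, spec.center_mm, np.asarray(spec.radii_mm))
        outer = _ellipsoid_mask(grids, spec.center_mm, spec.radii_mm)
        if spec.rim_suv is None:
            return outer, [(outer, spec.suv)]
        core = _ellipsoid_mask(
            grids, spec.center_mm, np.asarray(spec.radii_mm) * spec.core_fraction
        )
        return outer, [(outer, spec.rim_suv), (core, spec.suv)]
    if isinstance(spec, DumbbellSpec):
        _check_inside(extent, spec.center1_mm, spec.radius1_mm)
        _check_inside(extent, spec.center2_mm, spec.radius2_mm)
        s1 = _ellipsoid_mask(grids, spec.center1_mm, (spec.radius1_mm,) * 3)
        s2 = _ellipsoid_mask(grids, spec.center2_mm, (spec.radius2_mm,) * 3)
        bridge = _segment_distance(grids, spec.center1_mm, spec.center2_mm) \
            <= spec.bridge_radius_mm
        union = s1 | s2 | bridge
        return union, [(bridge, spec.bridge_suv), (s2, spec.suv2), (s1, spec.suv1)]
    raise TypeError(f"unknown lesion spec type {type(spec).__name__}")


def generate_phantom(spec: PhantomSpec) -> tuple[SuvVolume, PhantomTruth]:
    """Generate a deterministic SUV volume plus ground-truth masks.

    Structures must lie inside the grid and must not overlap each other
    (overlap would make the ground truth ambiguous).  The same spec and seed
    always produce the bit-identical volume.
    """
    shape = tuple(int(n) for n in spec.shape)
    spacing = tuple(float(s) for s in spec.spacing)
    extent = tuple((n - 1) * d for n, d in zip(shape, spacing))
    grids = _voxel_centers(shape, spacing)

    values = np.full(shape, spec.background_suv, dtype=np.float64)
    painted = np.zeros(shape, dtype=bool)
    lesion_masks: list[np.ndarray] = []
    organ_masks: dict[str, np.ndarray] = {}

    for organ in spec.organs:
        _check_inside(extent, organ.center_mm, np.asarray(organ.radii_mm))
        mask = _ellipsoid_mask(grids, organ.center_mm, organ.radii_mm)
        if (mask & painted).any():
            raise PhantomError(f"organ {organ.name!r} overlaps another structure")
        values[mask] = organ.suv
        painted |= mask
        organ_masks[organ.name] = mask

    for i, lesion in enumerate(spec.lesions):
        mask, fills = _paint_lesion(lesion, grids, extent)
        if (mask & painted).any():
            raise PhantomError(f"lesion {i} overlaps another structure")
        for sub, suv in fills:
            values[sub] = suv
        painted |= mask
        lesion_masks.append(mask)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)
    values = np.clip(values, 0.0, None)

    volume = SuvVolume(values, spacing)
    truth = PhantomTruth(
        lesion_masks=[
            VoiMask.from_volume(volume, m, method="truth", note=f"lesion {i}")
            for i, m in enumerate(lesion_masks)
        ],
        organ_masks={
            name: VoiMask.from_volume(volume, m, method="truth", note=name)
            for name, m in organ_masks.items()
        },
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Observer simulation


@dataclass(frozen=True)
class ObserverModel:
    """Stochastic model of one observer's behavior.

    ``p_click_suboptimal`` is the probability that, on a given lesion, the
    observer clicks in a visually avid part of the lesion that is not its
    true hottest part — the dominant source of disagreement for
    percentage-of-max segmentation of heterogeneous lesions (roughly a third
    of commonly selected lesions in practice).  Keeping a physiological
    region as tumor is rare (nobody mistakes the brain for lymphoma);
    clearing a genuine tumor region as non-tumor is the more common
    judgment-call error.  All rates are order-of-magnitude defaults; a
    zero-jitter, zero-error model reproduces the ground truth exactly.
    """

    click_jitter_sd_mm: float = 4.0
    p_click_suboptimal: float = 0.3
    p_keep_organ: float = 0.02     # physiological region kept as tumor
    p_clear_tumor: float = 0.02    # tumor region cleared as physiological
    miss_prob_small: float = 0.2   # P(miss) for lesions below small_lesion_ml
    miss_prob_large: float = 0.0
    small_lesion_ml: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_click_suboptimal, self.p_keep_organ, self.p_clear_tumor,
                  self.miss_prob_small, self.miss_prob_large):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    def miss_probability(self, volume_ml: float) -> float:
        return self.miss_prob_small if volume_ml < self.small_lesion_ml \
            else self.miss_prob_large


@dataclass
class ObserverActions:
    """Workflow inputs produced by one simulated observer on one phantom."""

    clicks: list[SeedClick]
    b_edits: EditScript
    c_edits: EditScript
    missed_lesions: list[int]


def simulate_observer(
    model: ObserverModel,
    truth: PhantomTruth,
    volume: SuvVolume,
    seed: int | None = None,
    regions: list[Region] | None = None,
    patient_id: str = "",
    observer_id: str = "",
    max_jitter_tries: int = 100,
) -> ObserverActions:
    """Simulate one observer's clicks and edit scripts on one phantom.

    Clicks: for each non-missed lesion, the hottest true voxel perturbed by
    isotropic Gaussian jitter, redrawn until it lands inside the lesion
    (``max_jitter_tries`` attempts, after which the lesion counts as
    missed).  Workflow-B edits: each preselected region is classified by its
    dominant ground-truth overlap and cleared (or erroneously kept/cleared)
    according to the misclassification probabilities.  Workflow-C edits: an
    adaptive-segmentation add for every clicked lesion the preselection did
    not cover.

    Click-related draws and edit-decision draws come from independent child
    streams of ``seed``, so Workflow-B behavior does not depend on the click
    parameters.
    """
    ss = np.random.SeedSequence(model.seed if seed is None else seed)
    click_rng, edit_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    spacing = np.asarray(volume.spacing)

    clicks: list[SeedClick] = []
    missed: list[int] = []
    click_by_lesion: dict[int, SeedClick] = {}
    for i, lesion in enumerate(truth.lesion_masks):
        if click_rng.uniform() < model.miss_probability(lesion.volume_ml):
            missed.append(i)
            continue
        hot = _lexicographic_argmax(volume.values, lesion.values)
        target = hot
        if model.p_click_suboptimal > 0 and \
                click_rng.uniform() < model.p_click_suboptimal:
            # Click lands in a visually avid part of the lesion that need not
            # contain the true maximum (heterogeneous-lesion behavior).
            avid = np.argwhere(lesion.values & (volume.values >= 4.0))
            if len(avid):
                target = tuple(int(c) for c in avid[click_rng.integers(len(avid))])
        index = target
        if model.click_jitter_sd_mm > 0:
            index = None
            for _ in range(max_jitter_tries):
                offset = click_rng.normal(0.0, model.click_jitter_sd_mm, 3) / spacing
                cand = tuple(int(round(c + o)) for c, o in zip(target, offset))
                if volume.contains_index(cand) and lesion.values[cand]:
                    index = cand
                    break
            if index is None:
                missed.append(i)
                continue
        click = SeedClick(index, observer_id=observer_id, patient_id=patient_id)
        clicks.append(click)
        click_by_lesion[i] = click

    if regions is None:
        regions = preselect_regions(volume, compute_peak=False)

    organ_union = truth.organ_union()
    lesion_union = truth.lesion_union()
    b_ops = []
    for region in regions:
        organ_overlap = int(np.count_nonzero(region.mask.values & organ_union))
        tumor_overlap = int(np.count_nonzero(region.mask.values & lesion_union))
        is_physiological = organ_overlap > tumor_overlap
        u = edit_rng.uniform()
        if is_physiological:
            if u >= model.p_keep_organ:
                b_ops.append(ClearRegion(region.region_id))
        else:
            if u < model.p_clear_tumor:
                b_ops.append(ClearRegion(region.region_id))

    preselected_union = np.zeros(volume.shape, dtype=bool)
    for region in regions:
        preselected_union |= region.mask.values
    c_ops = []
    for i, lesion in enumerate(truth.lesion_masks):
        if i in click_by_lesion and not (lesion.values & preselected_union).any():
            c_ops.append(AddLesionA50P(click_by_lesion[i].index))

    return ObserverActions(
        clicks=clicks,
        b_edits=EditScript(b_ops),
        c_edits=EditScript(c_ops),
        missed_lesions=missed,
    )


# ---------------------------------------------------------------------------
# Random study phantoms


def _default_organs(extent) -> tuple[OrganSpec, ...]:
    ex, ey, ez = extent
    return (
        OrganSpec("brain", (ex / 2, ey / 2, ez - 28), (22.0, 22.0, 22.0), 8.0),
        OrganSpec("bladder", (ex / 2, ey / 2, 26.0), (14.0, 14.0, 14.0), 12.0),
        OrganSpec("liver", (ex * 0.3, ey / 2, ez * 0.45), (34.0, 28.0, 24.0), 5.0),
    )


def sample_phantom_spec(
    rng: np.random.Generator,
    shape=(64, 64, 48),
    spacing=(4.0, 4.0, 4.0),
    n_lesions_range=(1, 8),
    p_dumbbell: float = 0.4,
    p_core_rim: float = 0.2,
    background_suv: float = 0.5,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> PhantomSpec:
    """Draw a random patient phantom: organs plus a variable mix of uniform,
    core+rim and dumbbell lesions placed without overlap (rejection
    sampling; a lesion that cannot be placed is dropped)."""
    extent = tuple((n - 1) * d for n, d in zip(shape, spacing))
    ex, ey, ez = extent
    organs = _default_organs(extent)
    # Occupied space as capsules (p1, p2, radius); spheres have p1 == p2.
    occupied = [
        (np.asarray(o.center_mm), np.asarray(o.center_mm), float(max(o.radii_mm)))
        for o in organs
    ]

    def _point_segment_dist(c, p1, p2) -> float:
        d = p2 - p1
        L2 = float(d @ d)
        t = 0.0 if L2 == 0 else float(np.clip((c - p1) @ d / L2, 0.0, 1.0))
        return float(np.linalg.norm(c - (p1 + t * d)))

    def fits(center, radius) -> bool:
        c = np.asarray(center, dtype=float)
        return all(
            _point_segment_dist(c, p1, p2) > radius + orad + 6.0
            for p1, p2, orad in occupied
        )

    def fits_capsule(c1, c2, radius) -> bool:
        # Sample along the capsule axis; adequate at the 6 mm safety margin.
        a, b = np.asarray(c1, dtype=float), np.asarray(c2, dtype=float)
        return all(
            fits(a + t * (b - a), radius) for t in np.linspace(0.0, 1.0, 7)
        )

    def draw_center(radius):
        for _ in range(60):
            c = (
                rng.uniform(radius + 4, ex - radius - 4),
                rng.uniform(radius + 4, ey - radius - 4),
                rng.uniform(40.0, ez - 50.0),
            )
            if fits(c, radius):
                return c
        return None

    lesions: list = []
    n_lesions = int(rng.integers(n_lesions_range[0], n_lesions_range[1] + 1))
    for lesion_idx in range(n_lesions):
        u = rng.uniform()
        if u < p_dumbbell:
            # Small very-hot focus (lobe 1) attached to a larger moderately
            # avid mass (lobe 2): a click on the focus segments only the
            # focus at 41 % of its max, a click on the mass segments the
            # whole lesion.
            r1 = rng.uniform(5.0, 8.0)
            r2 = rng.uniform(14.0, 24.0)
            sep = r1 + r2 + rng.uniform(6.0, 12.0)
            placed = False
            for _ in range(60):
                c1 = draw_center(r1)
                if c1 is None:
                    break
                direction = rng.normal(size=3)
                direction[2] *= 0.3  # keep lobes in similar axial range
                direction /= np.linalg.norm(direction)
                c2 = tuple(np.asarray(c1) + sep * direction)
                if all(r2 + 4 <= c <= e - r2 - 4 for c, e in zip(c2, extent)) \
                        and fits(c2, r2) and fits_capsule(c1, c2, 5.0):
                    placed = True
                    break
            if not placed:
                continue
            lesions.append(
                DumbbellSpec(
                    center1_mm=c1,
                    center2_mm=c2,
                    radius1_mm=r1,
                    radius2_mm=r2,
                    suv1=rng.uniform(14.0, 26.0),
                    suv2=rng.uniform(8.0, 12.0),
                    bridge_suv=rng.uniform(4.2, 5.0),
                    bridge_radius_mm=rng.uniform(3.0, 4.0),
                )
            )
            occupied.append((np.asarray(c1), np.asarray(c1), r1))
            occupied.append((np.asarray(c2), np.asarray(c2), r2))
            occupied.append((np.asarray(c1), np.asarray(c2), 5.0))
        elif u < p_dumbbell + p_core_rim:
            r = rng.uniform(10.0, 20.0)
            c = draw_center(r)
            if c is None:
                continue
            lesions.append(
                LesionSpec(
                    center_mm=c,
                    radii_mm=(r, r * rng.uniform(0.8, 1.0), r * rng.uniform(0.8, 1.0)),
                    suv=rng.uniform(12.0, 25.0),
                    rim_suv=rng.uniform(4.5, 7.0),
                )
            )
            occupied.append((np.asarray(c), np.asarray(c), r))
        else:
            # First lesion at least ~4 ml so every patient has measurable
            # (preselectable) disease; later ones range down to ~0.5 ml.
            r = rng.uniform(10.0 if lesion_idx == 0 else 5.0, 24.0)
            c = draw_center(r)
            if c is None:
                continue
            lesions.append(
                LesionSpec(center_mm=c, radii_mm=(r, r, r), suv=rng.uniform(5.0, 20.0))
            )
            occupied.append((np.asarray(c), np.asarray(c), r))

    if seed is None:
        seed = int(rng.integers(0, 2**31 - 1))
    return PhantomSpec(
        shape=tuple(shape),
        spacing=tuple(spacing),
        background_suv=background_suv,
        noise_sd=noise_sd,
        lesions=tuple(lesions),
        organs=organs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Full reliability experiment


@dataclass
class StudyConfig:
    """Design of one simulated interobserver study.

    Defaults mirror the reference design: 12 patients, 3 observers,
    Workflow A with all six methods, automated preselection (B) and manual
    modification (C1).
    """

    n_patients: int = 12
    n_observers: int = 3
    observer_model: ObserverModel = field(default_factory=ObserverModel)
    methods: tuple = tuple(m.value for m in MethodId)
    workflows: tuple = ("A", "B", "C1")
    shape: tuple = (64, 64, 48)
    spacing: tuple = (4.0, 4.0, 4.0)
    n_lesions_range: tuple = (1, 8)
    p_dumbbell: float = 0.4
    p_core_rim: float = 0.2
    background_suv: float = 0.5
    noise_sd: float = 0.1
    master_seed: int = 0
    phantom_sampler: Callable | None = None


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    report: pd.DataFrame
    formatted: pd.DataFrame


def run_reliability_experiment(config: StudyConfig) -> ExperimentResult:
    """Run the full simulated study: phantoms x observers x workflows.

    Every cell is reproducible from the master seed via deterministic
    per-patient / per-observer child seeds.  Cells whose Workflow A has no
    clicks (every lesion missed) are recorded as missing; the ICC for a
    method is then computed only if its patient x observer layout is
    complete.
    """
    if config.n_patients < 2 or config.n_observers < 2:
        raise ValueError("need at least 2 patients and 2 observers")
    sampler = config.phantom_sampler or sample_phantom_spec
    master = np.random.SeedSequence(config.master_seed)
    patient_seeds = master.spawn(config.n_patients)
    rows = []
    for p_idx, pss in enumerate(patient_seeds):
        patient = f"P{p_idx + 1:02d}"
        children = pss.spawn(config.n_observers + 1)
        spec_rng = np.random.default_rng(children[0])
        spec = sampler(
            spec_rng,
            shape=config.shape,
            spacing=config.spacing,
            n_lesions_range=config.n_lesions_range,
            p_dumbbell=config.p_dumbbell,
            p_core_rim=config.p_core_rim,
            background_suv=config.background_suv,
            noise_sd=config.noise_sd,
        )
        volume, truth = generate_phantom(spec)
        regions = preselect_regions(volume, compute_peak=False)
        for o_idx in range(config.n_observers):
            observer = f"O{o_idx + 1}"
            obs_seed = int(children[o_idx + 1].generate_state(1)[0] & 0x7FFFFFFF)
            actions = simulate_observer(
                config.observer_model,
                truth,
                volume,
                seed=obs_seed,
                regions=regions,
                patient_id=patient,
                observer_id=observer,
            )
            if "A" in config.workflows:
                if actions.clicks:
                    for res in run_workflow_a(
                        volume,
                        actions.clicks,
                        methods=list(config.methods),
                        patient_id=patient,
                        observer_id=observer,
                    ):
                        rows.append(
                            (patient, observer, "A", res.method, res.mtv_ml, res.tlg)
                        )
                else:
                    for m in config.methods:
                        rows.append((patient, observer, "A", m, np.nan, np.nan))
            b_res = None
            if "B" in config.workflows or "C1" in config.workflows:
                b_res = run_workflow_b(
                    volume,
                    actions.b_edits,
                    regions=regions,
                    patient_id=patient,
                    observer_id=observer,
                )
            if "B" in config.workflows:
                rows.append(
                    (patient, observer, "B", "preselect", b_res.mtv_ml, b_res.tlg)
                )
            if "C1" in config.workflows:
                c_res = run_workflow_c(volume, b_res, actions.c_edits)
                rows.append(
                    (patient, observer, "C1", "final", c_res.mtv_ml, c_res.tlg)
                )
    table = pd.DataFrame(
        rows, columns=["patient", "observer", "workflow", "method", "MTV", "TLG"]
    )
    report = reliability_report(table)
    return ExperimentResult(table=table, report=report, formatted=format_report(report))
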