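"""Per-lesion and whole-volume segmentation operators.

Implements the four threshold-based lesion segmentation methods commonly
used for lymphoma MTV measurement, each grown as a 3D connected component
from a single observer click:

* ``41max``  — threshold at 41 % of the lesion SUVmax;
* ``a50p``   — adaptive threshold at 50 % of SUVpeak with local background
  correction, iterated to a fixed point;
* ``suv25``  — fixed threshold SUV >= 2.5;
* ``suv40``  — fixed threshold SUV >= 4.0;

plus majority-vote consensus masks (``mv2``/``mv3``: voxels included by at
least 2 / 3 of the four methods) and the fully automated preselection of all
FDG-avid structures (connected components with SUV >= 4.0 and volume >= 3 ml).

Clicks are first stabilised by a robust-local-maximum search: the click is
grown at 70 % of the clicked value and the hottest voxel of that region is
used as the seed, so results depend little on the exact voxel clicked.

Conventions: 26-connectivity by default (configurable to 6), thresholds
compare with >= (a voxel equal to the threshold is included), and ties for a
maximum break to the smallest lexicographic index so every operator is
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy import ndimage as ndi

from .image import SuvVolume, VoiMask
from .metrics import suv_max, suv_mean, tlg

__all__ = [
    "MethodId",
    "Region",
    "SegmentationError",
    "SeedInBackgroundError",
    "robust_local_max",
    "segment_fixed_threshold",
    "segment_pct_max",
    "segment_a50p",
    "suv_peak",
    "majority_vote",
    "preselect_regions",
    "PRESELECT_SUV_MIN",
    "PRESELECT_VOL_MIN_ML",
]

#: Preselection defaults: SUV >= 4.0 and component volume >= 3 ml (inclusive).
PRESELECT_SUV_MIN = 4.0
PRESELECT_VOL_MIN_ML = 3.0

#: Volume of the SUVpeak averaging sphere (PERCIST-style), in ml.
SUV_PEAK_SPHERE_ML = 1.0


class MethodId(str, Enum):
    """Identifier of a segmentation method.

    ``MV2``/``MV3`` are consensus labels produced only by
    :func:`majority_vote`, never by a threshold call.
    """

    FORTYONE_MAX = "41max"
    A50P = "a50p"
    SUV25 = "suv25"
    SUV40 = "suv40"
    MV2 = "mv2"
    MV3 = "mv3"

    @classmethod
    def base_methods(cls) -> tuple["MethodId", ...]:
        return (cls.FORTYONE_MAX, cls.A50P, cls.SUV25, cls.SUV40)


class SegmentationError(RuntimeError):
    """A segmentation could not be produced (e.g. seed below threshold)."""


class SeedInBackgroundError(SegmentationError):
    """The click landed on a zero-SUV voxel; no region can be grown."""


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndi.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def _component_of_seed(above: np.ndarray, seed, connectivity: int) -> np.ndarray:
    """Connected component of the boolean field ``above`` containing ``seed``."""
    labels, _ = ndi.label(above, structure=_structure(connectivity))
    lab = labels[tuple(seed)]
    if lab == 0:
        raise SegmentationError(f"seed {tuple(seed)} not inside the thresholded set")
    return labels == lab


def _lexicographic_argmax(values: np.ndarray, within: np.ndarray):
    """Index of the maximum of ``values`` over ``within`` (bool mask); ties
    break to the smallest (i, j, k) in lexicographic order."""
    vals = np.where(within, values, -np.inf)
    # np.argmax on the C-ordered flat array already returns the first (i.e.
    # lexicographically smallest) occurrence of the maximum.
    flat = int(np.argmax(vals))
    return tuple(int(c) for c in np.unravel_index(flat, values.shape))


# ---------------------------------------------------------------------------
# Seed refinement


def robust_local_max(
    volume: SuvVolume, click, connectivity: int = 26
) -> tuple[int, int, int]:
    """Refine a click to the hottest voxel of its local uptake region.

    The region is grown from the click at a threshold of 70 % of the clicked
    SUV; the returned index is the maximum-SUV voxel of that region.  This
    makes downstream segmentations insensitive to the exact voxel clicked,
    as long as the click lands where uptake is within 70 % of the local peak
    and connected to it.
    """
    from .image import SeedClick

    raw = click.index if isinstance(click, SeedClick) else click
    index = tuple(int(c) for c in raw)
    if not volume.contains_index(index):
        raise ValueError(f"click {index} outside volume bounds {volume.shape}")
    v_click = volume.suv_at(index)
    if v_click <= 0:
        raise SeedInBackgroundError(f"seed in background: SUV({index}) = {v_click}")
    region = _component_of_seed(volume.values >= 0.7 * v_click, index, connectivity)
    return _lexicographic_argmax(volume.values, region)


# ---------------------------------------------------------------------------
# Threshold methods


def segment_fixed_threshold(
    volume: SuvVolume, seed, t: float, connectivity: int = 26
) -> VoiMask:
    """Connected component of {SUV >= t} containing the seed."""
    seed = tuple(int(c) for c in seed)
    if not volume.contains_index(seed):
        raise ValueError(f"seed {seed} outside volume bounds {volume.shape}")
    if volume.suv_at(seed) < t:
        raise SegmentationError(
            f"seed SUV {volume.suv_at(seed):.2f} below threshold {t:.2f}: empty mask"
        )
    comp = _component_of_seed(volume.values >= t, seed, connectivity)
    method = {2.5: MethodId.SUV25.value, 4.0: MethodId.SUV40.value}.get(
        float(t), f"suv>={t:g}"
    )
    return VoiMask.from_volume(volume, comp, method=method)


def segment_pct_max(
    volume: SuvVolume, seed, fraction: float = 0.41, connectivity: int = 26
) -> VoiMask:
    """Percentage-of-SUVmax segmentation (default 41 %).

    The seed is expected to be refined by :func:`robust_local_max`; its SUV
    is taken as the lesion SUVmax defining the threshold.
    """
    seed = tuple(int(c) for c in seed)
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    v_seed = volume.suv_at(seed)
    if v_seed <= 0:
        raise SeedInBackgroundError(f"seed in background: SUV({seed}) = {v_seed}")
    mask = segment_fixed_threshold(volume, seed, fraction * v_seed, connectivity)
    return replace(mask, method=MethodId.FORTYONE_MAX.value if fraction == 0.41
                   else f"{fraction:.0%}max")


def segment_a50p(
    volume: SuvVolume,
    seed,
    exclude: VoiMask | None = None,
    connectivity: int = 26,
    max_iter: int = 10,
    init_mask: VoiMask | None = None,
) -> VoiMask:
    """Adaptive segmentation at 50 % of SUVpeak with local background correction.

    Starting from a provisional region grown at half the seed SUV (or from
    ``init_mask``), the method iterates

        T = 0.5 * (SUVpeak(mask) - BG) + BG

    where BG is the mean SUV in a 2-voxel-thick shell starting 1 voxel
    outside the current mask (voxels in ``exclude`` — e.g. other lesions —
    are left out of the shell), and the mask is regrown as the connected
    component of {SUV >= T} containing the seed, until a fixed point or
    ``max_iter`` iterations.  Non-convergence returns the last mask with a
    warning note rather than failing.
    """
    seed = tuple(int(c) for c in seed)
    v_seed = volume.suv_at(seed)
    if v_seed <= 0:
        raise SeedInBackgroundError(f"seed in background: SUV({seed}) = {v_seed}")
    if init_mask is not None:
        init_mask.check_aligned(volume)
        mask = init_mask.values.copy()
        if not mask[seed]:
            raise SegmentationError("init_mask does not contain the seed")
    else:
        mask = _component_of_seed(volume.values >= 0.5 * v_seed, seed, connectivity)
    note = ""
    for _ in range(max_iter):
        peak = suv_peak(volume, VoiMask.from_volume(volume, mask))
        bg = _shell_background(volume, mask, exclude)
        t = 0.5 * (peak - bg) + bg
        if volume.suv_at(seed) < t:
            # Threshold climbed past the seed; keep the last valid mask.
            note = "a50p: threshold exceeded seed SUV; kept last mask"
            break
        new = _component_of_seed(volume.values >= t, seed, connectivity)
        if np.array_equal(new, mask):
            break
        mask = new
    else:
        note = f"a50p: no fixed point after {max_iter} iterations"
        warnings.warn(note, stacklevel=2)
    return VoiMask.from_volume(volume, mask, method=MethodId.A50P.value, note=note)


def _shell_background(
    volume: SuvVolume, mask: np.ndarray, exclude: VoiMask | None
) -> float:
    """Mean SUV in a 2-voxel shell starting 1 voxel outside ``mask``."""
    struct = ndi.generate_binary_structure(3, 3)
    inner = ndi.binary_dilation(mask, struct, iterations=1)
    outer = ndi.binary_dilation(inner, struct, iterations=2)
    shell = outer & ~inner
    if exclude is not None:
        shell &= ~exclude.values
    if not shell.any():
        return 0.0
    return float(volume.values[shell].mean(dtype=np.float64))


# ---------------------------------------------------------------------------
# SUVpeak


def _sphere_offsets(spacing, sphere_ml: float) -> np.ndarray:
    """Voxel offsets whose centers lie within the averaging-sphere radius."""
    r = (3.0 * sphere_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    dx, dy, dz = spacing
    ni, nj, nk = (int(np.floor(r / s)) for s in spacing)
    ii, jj, kk = np.mgrid[-ni : ni + 1, -nj : nj + 1, -nk : nk + 1]
    dist2 = (ii * dx) ** 2 + (jj * dy) ** 2 + (kk * dz) ** 2
    sel = dist2 <= r * r
    return np.stack([ii[sel], jj[sel], kk[sel]], axis=1)


def suv_peak(
    volume: SuvVolume, lesion: VoiMask, sphere_ml: float = SUV_PEAK_SPHERE_ML
) -> float:
    """SUVpeak: the highest mean SUV in a 1 ml sphere centered in the lesion.

    Sphere centers range over lesion voxels; sphere membership is by
    voxel-center distance to the center.  Sphere voxels may extend beyond the
    lesion (they average whatever surrounds it); voxels outside the grid are
    ignored, i.e. the mean is taken over the in-grid part of the sphere.
    """
    lesion.check_aligned(volume)
    if lesion.voxel_count == 0:
        raise ValueError("SUVpeak undefined for an empty lesion")
    offsets = _sphere_offsets(volume.spacing, sphere_ml)
    # Evaluate by convolution over a crop around the lesion: sum of SUVs and
    # count of in-grid sphere voxels per candidate center.
    idx = np.argwhere(lesion.values)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    margin = np.abs(offsets).max(axis=0)
    clo = np.maximum(lo - margin, 0)
    chi = np.minimum(hi + margin, volume.shape)
    crop = volume.values[clo[0]:chi[0], clo[1]:chi[1], clo[2]:chi[2]].astype(np.float64)
    kernel = _offsets_to_kernel(offsets)
    sums = ndi.convolve(crop, kernel, mode="constant", cval=0.0)
    counts = ndi.convolve(np.ones_like(crop), kernel, mode="constant", cval=0.0)
    # Lesion centers sit >= margin inside the crop except where the crop was
    # clipped at the true grid boundary, where the count correctly shrinks to
    # the in-grid part of the sphere.
    means = sums / counts
    lesion_crop = lesion.values[clo[0]:chi[0], clo[1]:chi[1], clo[2]:chi[2]]
    return float(means[lesion_crop].max())


def _offsets_to_kernel(offsets: np.ndarray) -> np.ndarray:
    half = np.abs(offsets).max(axis=0)
    kernel = np.zeros(2 * half + 1)
    kernel[tuple((offsets + half).T)] = 1.0
    # scipy's convolve correlates with the flipped kernel; the sphere kernel
    # is symmetric so no explicit flip is needed.
    return kernel


# ---------------------------------------------------------------------------
# Consensus


def majority_vote(masks: list[VoiMask], k: int) -> VoiMask:
    """Mask of voxels present in at least ``k`` of the input masks.

    ``k = 2`` / ``k = 3`` over the four base methods give the MV2 / MV3
    consensus volumes; ``k = 1`` is the union and ``k = len(masks)`` the
    intersection.
    """
    if not masks:
        raise ValueError("majority_vote requires at least one mask")
    if not 1 <= k <= len(masks):
        raise ValueError(f"k={k} out of range for {len(masks)} masks")
    first = masks[0]
    for m in masks[1:]:
        first.check_aligned(m)
    counts = np.zeros(first.shape, dtype=np.int16)
    for m in masks:
        counts += m.values
    method = {2: MethodId.MV2.value, 3: MethodId.MV3.value}.get(k, f"mv{k}")
    return replace(first, values=counts >= k, method=method, note="")


# ---------------------------------------------------------------------------
# Automated preselection


@dataclass(frozen=True)
class Region:
    """A preselected FDG-avid structure: one supra-threshold 3D component.

    A *region* is any component passing the SUV/volume preselection; whether
    it is tumor (a *lesion*) or physiological uptake (brain, bladder, ...)
    is an observer decision made downstream.
    """

    region_id: int
    mask: VoiMask
    suv_max: float
    suv_peak: float
    suv_mean: float
    volume_ml: float
    tlg: float
    centroid: tuple[float, float, float]


def preselect_regions(
    volume: SuvVolume,
    suv_min: float = PRESELECT_SUV_MIN,
    vol_min_ml: float = PRESELECT_VOL_MIN_ML,
    connectivity: int = 26,
    compute_peak: bool = True,
) -> list[Region]:
    """Fully automated preselection of FDG-avid structures.

    All connected components of {SUV >= suv_min} with volume >= vol_min_ml
    (inclusive), each with SUVmax/SUVpeak/SUVmean/volume/TLG, ordered by
    descending volume with ties broken by lexicographic centroid.  An empty
    list is a valid result.
    """
    labels, n = ndi.label(volume.values >= suv_min, structure=_structure(connectivity))
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())
    vox_ml = volume.voxel_volume_ml
    keep = [lab for lab in range(1, n + 1) if counts[lab] * vox_ml >= vol_min_ml]
    regions: list[Region] = []
    for lab in keep:
        mask = VoiMask.from_volume(volume, labels == lab, method="preselect")
        centroid = tuple(float(c) for c in np.argwhere(mask.values).mean(axis=0))
        regions.append(
            Region(
                region_id=0,  # assigned after sorting
                mask=mask,
                suv_max=suv_max(volume, mask),
                suv_peak=suv_peak(volume, mask) if compute_peak else float("nan"),
                suv_mean=suv_mean(volume, mask),
                volume_ml=mask.volume_ml,
                tlg=tlg(volume, mask),
                centroid=centroid,
            )
        )
    regions.sort(key=lambda r: (-r.volume_ml, r.centroid))
    return [replace_region_id(r, i + 1) for i, r in enumerate(regions)]


def replace_region_id(region: Region, region_id: int) -> Region:
    from dataclasses import replace as dc_replace

    return dc_replace(region, region_id=region_id)
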