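import numpy as np
import pytest
from skimage import measure

from petmtv import (
    SegmentationError,
    SeedInBackgroundError,
    SuvVolume,
    VoiMask,
    majority_vote,
    preselect_regions,
    robust_local_max,
    segment_a50p,
    segment_fixed_threshold,
    segment_pct_max,
    suv_peak,
)

from conftest import cube_volume, digitized_sphere, random_mask


class TestRobustLocalMax:
    def test_climbs_to_connected_hotter_voxel(self):
        vals = np.zeros((10, 10, 10), np.float32)
        vals[4, 4, 4] = 8.0
        vals[4, 4, 5] = 10.0
        vol = SuvVolume(vals, (4, 4, 4))
        assert robust_local_max(vol, (4, 4, 4)) == (4, 4, 5)

    def test_click_on_hottest_voxel_is_identity(self):
        vol = cube_volume(background=0.0)
        vals = vol.values.copy()
        vals[5, 5, 5] = 9.0
        vol = SuvVolume(vals, vol.spacing)
        assert robust_local_max(vol, (5, 5, 5)) == (5, 5, 5)

    def test_background_click_rejected(self):
        vol = cube_volume(background=0.0)
        with pytest.raises(SeedInBackgroundError):
            robust_local_max(vol, (0, 0, 0))

    def test_all_core_clicks_map_to_one_index(self):
        # Smooth single-peak lesion on a 20^3 grid: every in-lesion click with
        # SUV >= 0.7 * SUVmax must refine to the same (unique) maximum.
        n = 20
        ax = np.arange(n)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        d2 = (gx - 9.3) ** 2 + (gy - 10.1) ** 2 + (gz - 9.7) ** 2
        vals = np.where(d2 <= 49, 10.0 * np.exp(-d2 / 100.0), 0.0).astype(np.float32)
        vol = SuvVolume(vals, (4, 4, 4))
        suvmax = vals.max()
        top = robust_local_max(vol, tuple(np.unravel_index(vals.argmax(), vals.shape)))
        clicks = np.argwhere(vals >= 0.7 * suvmax)
        assert len(clicks) > 20
        for c in clicks:
            assert robust_local_max(vol, tuple(c)) == top


class TestFixedThreshold:
    def test_uniform_cube_all_thresholds_below_suv(self):
        vol = cube_volume()  # SUV 5 cube of 27 voxels on background 1, 1 ml voxels
        m25 = segment_fixed_threshold(vol, (5, 5, 5), 2.5)
        assert m25.voxel_count == 27
        assert m25.volume_ml == pytest.approx(27.00)
        m40 = segment_fixed_threshold(vol, (5, 5, 5), 4.0)
        assert np.array_equal(m25.values, m40.values)

    def test_seed_below_threshold_is_error(self):
        vol = cube_volume()
        with pytest.raises(SegmentationError, match="below threshold"):
            segment_fixed_threshold(vol, (0, 0, 0), 2.5)

    def test_digitized_sphere_volume_within_5pct(self):
        vol, inside = digitized_sphere(radius_mm=20.0, suv=10.0, spacing=(2, 2, 2))
        seed = tuple(np.argwhere(inside)[0])
        mask = segment_fixed_threshold(vol, seed, 4.0)
        analytic = 4.0 / 3.0 * np.pi * 2.0 ** 3  # 33.51 ml
        # voxel-count oracle over the analytic sphere indicator
        oracle_ml = inside.sum() * vol.voxel_volume_ml
        assert mask.volume_ml == pytest.approx(oracle_ml)
        assert abs(mask.volume_ml - analytic) / analytic < 0.05

    def test_threshold_monotonicity(self):
        vol = cube_volume(suv=6.0)
        lo = segment_fixed_threshold(vol, (5, 5, 5), 2.5)
        hi = segment_fixed_threshold(vol, (5, 5, 5), 4.0)
        assert not (hi.values & ~lo.values).any()


class TestPctMax:
    def test_uniform_lesion_excludes_background(self):
        vol = cube_volume(suv=10.0, background=1.0)
        mask = segment_pct_max(vol, (5, 5, 5))  # threshold 4.1
        assert mask.voxel_count == 27

    def test_cool_rim_excluded(self):
        vol = cube_volume(suv=10.0, background=0.0, shape=(14, 14, 14))
        vals = vol.values.copy()
        vals[3:8, 3:8, 3:8] = np.where(vals[3:8, 3:8, 3:8] == 10.0, 10.0, 3.0)
        vol = SuvVolume(vals, vol.spacing)
        mask = segment_pct_max(vol, (5, 5, 5))
        assert set(np.unique(vol.values[mask.values])) == {10.0}

    def test_two_lobe_clicks_agree_after_refinement(self):
        # Two lobes connected above 70% of the max: refinement unifies clicks.
        vals = np.zeros((24, 12, 12), np.float32)
        vals[4:9, 4:9, 4:9] = 9.0     # lobe A
        vals[9:11, 4:9, 4:9] = 8.0    # bridge, 8 >= 0.7*9
        vals[11:16, 4:9, 4:9] = 10.0  # lobe B (hotter)
        vol = SuvVolume(vals, (4, 4, 4))
        seed_a = robust_local_max(vol, (5, 5, 5))
        seed_b = robust_local_max(vol, (13, 5, 5))
        assert seed_a == seed_b
        ma = segment_pct_max(vol, seed_a)
        mb = segment_pct_max(vol, seed_b)
        assert np.array_equal(ma.values, mb.values)


class TestA50P:
    def test_background_free_reduces_to_half_peak(self):
        vol = cube_volume(shape=(20, 20, 20), lo=(5, 5, 5), hi=(14, 14, 14),
                          suv=10.0, background=0.0, spacing=(4, 4, 4))
        mask = segment_a50p(vol, (8, 8, 8))
        assert mask.voxel_count == 9 ** 3
        assert mask.note == ""

    def test_background_corrected_threshold(self):
        # Uniform SUV-10 lesion on background 2: T = 0.5*(10-2)+2 = 6 keeps the
        # lesion and excludes the background.
        vol = cube_volume(shape=(22, 22, 22), lo=(6, 6, 6), hi=(16, 16, 16),
                          suv=10.0, background=2.0, spacing=(4, 4, 4))
        mask = segment_a50p(vol, (10, 10, 10))
        assert mask.voxel_count == 10 ** 3
        assert set(np.unique(vol.values[mask.values])) == {10.0}

    def test_fixed_point_property(self):
        vol = cube_volume(shape=(22, 22, 22), lo=(6, 6, 6), hi=(16, 16, 16),
                          suv=10.0, background=2.0, spacing=(4, 4, 4))
        converged = segment_a50p(vol, (10, 10, 10))
        again = segment_a50p(vol, (10, 10, 10), init_mask=converged)
        assert np.array_equal(again.values, converged.values)


class TestSuvPeak:
    def test_uniform_large_lesion(self):
        vol = cube_volume(shape=(30, 30, 30), lo=(5, 5, 5), hi=(25, 25, 25),
                          suv=10.0, background=0.0, spacing=(4, 4, 4))
        lesion = VoiMask.from_volume(vol, vol.values > 0)
        assert suv_peak(vol, lesion) == pytest.approx(10.0)

    def test_single_hot_voxel_averaged_down(self):
        vals = np.zeros((12, 12, 12), np.float32)
        vals[6, 6, 6] = 20.0
        vol = SuvVolume(vals, (4, 4, 4))
        lesion = VoiMask.from_volume(vol, vals > 0)
        assert suv_peak(vol, lesion) < 20.0

    def test_matches_exhaustive_brute_force(self, rng):
        from petmtv.segmentation import _sphere_offsets

        vals = (rng.gamma(2.0, 1.5, size=(14, 14, 14)) + 1).astype(np.float32)
        vals[4:10, 4:10, 4:10] += 8.0  # hot core
        vol = SuvVolume(vals, (4.0, 4.0, 4.0))
        lesion = VoiMask.from_volume(vol, vals >= 8.0)
        offsets = _sphere_offsets(vol.spacing, 1.0)
        best = -np.inf
        for c in np.argwhere(lesion.values):  # O(N*S) oracle
            acc, cnt = 0.0, 0
            for off in offsets:
                p = c + off
                if all(0 <= p[a] < vol.shape[a] for a in range(3)):
                    acc += float(vals[tuple(p)])
                    cnt += 1
            best = max(best, acc / cnt)
        assert suv_peak(vol, lesion) == pytest.approx(best, rel=1e-9)

    def test_empty_lesion_rejected(self):
        vol = cube_volume()
        with pytest.raises(ValueError):
            suv_peak(vol, VoiMask.from_volume(vol, np.zeros(vol.shape, bool)))


class TestMajorityVote:
    def test_definition_on_counted_voxel(self):
        vol = cube_volume(shape=(6, 6, 6))
        masks = []
        for present in ([1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 0, 0], [1, 0, 0, 0]):
            vals = np.zeros(vol.shape, bool)
            vals[1, 1, 1] = bool(present[0])
            vals[2, 2, 2] = bool(present[1])
            masks.append(VoiMask.from_volume(vol, vals))
        mv2 = majority_vote(masks, 2)
        mv3 = majority_vote(masks, 3)
        assert mv2.values[1, 1, 1] and mv2.values[2, 2, 2]
        assert not mv3.values[1, 1, 1] and not mv3.values[2, 2, 2]

    def test_identical_masks(self, rng):
        vol = cube_volume(shape=(8, 8, 8))
        m = random_mask(vol, rng)
        for k in (2, 3):
            assert np.array_equal(majority_vote([m] * 4, k).values, m.values)

    def test_counting_oracle_and_nesting(self, rng):
        vol = cube_volume(shape=(8, 8, 8))
        for _ in range(20):
            masks = [random_mask(vol, rng, 0.3) for _ in range(4)]
            counts = sum(m.values.astype(int) for m in masks)
            for k in range(1, 5):
                assert np.array_equal(majority_vote(masks, k).values, counts >= k)
            union = majority_vote(masks, 1).values
            inter = majority_vote(masks, 4).values
            mv2, mv3 = majority_vote(masks, 2).values, majority_vote(masks, 3).values
            assert not (mv3 & ~mv2).any()
            assert not (mv2 & ~union).any()
            assert np.array_equal(union, masks[0].values | masks[1].values
                                  | masks[2].values | masks[3].values)
            assert np.array_equal(inter, masks[0].values & masks[1].values
                                  & masks[2].values & masks[3].values)


class TestPreselect:
    def _blob_volume(self):
        # 10 mm voxels = 1 ml each: a 5 ml SUV-6 blob and a 2 ml SUV-8 blob
        # on SUV-1 background.
        vals = np.ones((24, 24, 24), np.float32)
        vals[2:7, 2, 2] = 6.0       # 5 voxels = 5 ml
        vals[12:14, 12, 12] = 8.0   # 2 voxels = 2 ml
        return SuvVolume(vals, (10.0, 10.0, 10.0))

    def test_volume_filter(self):
        vol = self._blob_volume()
        regions = preselect_regions(vol)
        assert len(regions) == 1
        assert regions[0].volume_ml == pytest.approx(5.0)
        assert regions[0].suv_max == pytest.approx(6.0)

    def test_all_background_gives_empty_list(self):
        vol = cube_volume(suv=3.5, background=1.0)
        assert preselect_regions(vol) == []

    def test_component_count_matches_independent_labeling_oracle(self, rng):
        from petmtv import PhantomSpec, LesionSpec, OrganSpec, generate_phantom

        spec = PhantomSpec(
            lesions=(
                LesionSpec((60, 60, 80), (12, 12, 12), 8.0),
                LesionSpec((160, 60, 80), (14, 14, 14), 12.0),
                LesionSpec((110, 170, 100), (10, 10, 10), 6.0),
            ),
            organs=(
                OrganSpec("brain", (126, 126, 160), (20, 20, 20), 8.0),
                OrganSpec("bladder", (126, 126, 26), (13, 13, 13), 12.0),
                OrganSpec("liver", (70, 126, 120), (24, 20, 18), 5.0),
            ),
            seed=7,
        )
        vol, _ = generate_phantom(spec)
        regions = preselect_regions(vol, compute_peak=False)
        labels = measure.label(vol.values >= 4.0, connectivity=3)
        big = sum(
            1
            for lab in range(1, labels.max() + 1)
            if (labels == lab).sum() * vol.voxel_volume_ml >= 3.0
        )
        assert len(regions) == big == 6

    def test_total_volume_nonincreasing_in_suv_min(self):
        vol = self._blob_volume()
        totals = [
            sum(r.volume_ml for r in preselect_regions(vol, suv_min=s, vol_min_ml=0.0))
            for s in (2.5, 4.0, 6.0, 8.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_region_suv_ordering_invariant(self):
        vol, inside = digitized_sphere(radius_mm=24.0, suv=10.0, spacing=(2, 2, 2),
                                       shape=(44, 44, 44))
        vals = vol.values.copy()
        # hot center so max > mean
        c = tuple(s // 2 for s in vol.shape)
        vals[c] = 15.0
        vol = SuvVolume(vals, vol.spacing)
        region = preselect_regions(vol)[0]
        assert region.suv_mean <= region.suv_peak <= region.suv_max
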