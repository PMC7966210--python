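import numpy as np
import pytest

from autoaspects import (
    ALL_REGIONS,
    CTVolume,
    Hemisphere,
    LesionSpec,
    PhantomSpec,
    ProbabilisticAtlas,
    Region,
    ThresholdSet,
    classify_region,
    detect_affected_hemisphere,
    include_voxel,
    region_weighted_mean,
    relative_difference,
    score_volume,
    simulate_volume,
)
from autoaspects.errors import EmptyRegionError, SpecificationError
from autoaspects.scorer import measure_all_regions


def tiny_atlas(weights_1d, region=Region.CN, hemi=Hemisphere.LEFT):
    """Single-map atlas over a (n, 1, 1) grid for arithmetic tests."""
    w = np.asarray(weights_1d, dtype=float).reshape(-1, 1, 1)
    return ProbabilisticAtlas(
        grid_shape=w.shape,
        voxel_spacing_mm=(1.0, 1.0, 1.0),
        weights={(region, hemi): w},
    )


def tiny_volume(hu_1d):
    return CTVolume(
        voxels=np.asarray(hu_1d, dtype=float).reshape(-1, 1, 1),
        voxel_spacing_mm=(1.0, 1.0, 1.0),
    )


class TestIncludeVoxel:
    def test_window_bounds(self):
        assert not include_voxel(9.99)
        assert not include_voxel(55.01)
        assert include_voxel(35.0)
        assert include_voxel(10.0)  # bounds are inclusive
        assert include_voxel(55.0)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            include_voxel(float("nan"))
        with pytest.raises(ValueError):
            include_voxel(float("inf"))

    def test_vectorized(self):
        out = include_voxel(np.array([5.0, 10.0, 30.0, 55.0, 60.0]))
        assert out.tolist() == [False, True, True, True, False]


class TestRegionWeightedMean:
    def test_constant_field_any_weights(self):
        atlas = tiny_atlas([0.3, 1.0, 0.7])
        m = region_weighted_mean(tiny_volume([40, 40, 40]), atlas, Region.CN, Hemisphere.LEFT)
        assert m.weighted_mean_hu == pytest.approx(40.0)
        assert m.excluded_voxel_count == 0

    def test_out_of_window_voxel_excluded(self):
        atlas = tiny_atlas([1.0, 1.0])
        m = region_weighted_mean(tiny_volume([30, 60]), atlas, Region.CN, Hemisphere.LEFT)
        assert m.weighted_mean_hu == pytest.approx(30.0)
        assert m.excluded_voxel_count == 1
        assert m.included_weight == pytest.approx(1.0)

    def test_hand_computed_weighted_mean(self):
        # (0.5*30 + 1.0*36 + 0.25*44) / 1.75 = 62/1.75
        atlas = tiny_atlas([0.5, 1.0, 0.25])
        m = region_weighted_mean(tiny_volume([30, 36, 44]), atlas, Region.CN, Hemisphere.LEFT)
        assert m.weighted_mean_hu == pytest.approx(62.0 / 1.75, abs=1e-12)

    def test_zero_weight_voxels_not_counted_as_excluded(self):
        # w = 0 voxels are skipped before HU testing (support voxels only)
        atlas = tiny_atlas([0.0, 1.0, 0.0])
        m = region_weighted_mean(tiny_volume([900, 35, -500]), atlas, Region.CN, Hemisphere.LEFT)
        assert m.weighted_mean_hu == pytest.approx(35.0)
        assert m.excluded_voxel_count == 0

    def test_fully_excluded_region_raises(self):
        atlas = tiny_atlas([1.0, 1.0])
        with pytest.raises(EmptyRegionError) as err:
            region_weighted_mean(tiny_volume([5, 70]), atlas, Region.CN, Hemisphere.LEFT)
        assert err.value.region == Region.CN

    def test_grid_mismatch_raises(self, atlas64):
        vol = tiny_volume([35, 35])
        with pytest.raises(SpecificationError):
            region_weighted_mean(vol, atlas64, Region.CN, Hemisphere.LEFT)

    def test_agrees_with_voxel_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            shape = tuple(rng.integers(3, 7, size=3))
            w = rng.uniform(0, 1, size=shape) * (rng.random(shape) < 0.7)
            if not (w > 0).any():
                continue
            hu = rng.uniform(-20, 90, size=shape)
            atlas = ProbabilisticAtlas(
                grid_shape=shape, voxel_spacing_mm=(1, 1, 1),
                weights={(Region.M2, Hemisphere.RIGHT): w},
            )
            vol = CTVolume(hu, (1, 1, 1))
            num = den = 0.0
            excluded = 0
            for idx in np.ndindex(shape):
                if w[idx] <= 0:
                    continue
                if 10.0 <= hu[idx] <= 55.0:
                    num += w[idx] * hu[idx]
                    den += w[idx]
                else:
                    excluded += 1
            if den == 0:
                with pytest.raises(EmptyRegionError):
                    region_weighted_mean(vol, atlas, Region.M2, Hemisphere.RIGHT)
                continue
            m = region_weighted_mean(vol, atlas, Region.M2, Hemisphere.RIGHT)
            assert m.weighted_mean_hu == pytest.approx(num / den, rel=1e-12)
            assert m.excluded_voxel_count == excluded


class TestRelativeDifference:
    def test_arithmetic_identities(self):
        assert relative_difference(33.04, 35.0) == pytest.approx(5.6, abs=1e-9)
        assert relative_difference(35.0, 35.0) == 0.0
        assert relative_difference(36.0, 35.0) == pytest.approx(-100.0 / 35.0, abs=1e-9)

    def test_non_positive_contralateral_raises(self):
        with pytest.raises(ValueError):
            relative_difference(30.0, 0.0)
        with pytest.raises(ValueError):
            relative_difference(30.0, -5.0)


class TestClassifyRegion:
    def test_boundary_is_inclusive(self):
        assert classify_region(5.6, 5.6)
        assert not classify_region(5.59, 5.6)
        assert not classify_region(-3.0, 4.7)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify_region(1.0, 0.0)


class TestThresholdSet:
    def test_grouped_routing(self):
        ts = ThresholdSet()
        assert ts.for_region(Region.CN) == 5.6
        assert ts.for_region(Region.M4) == 4.7

    def test_single_routing(self):
        ts = ThresholdSet(mode="single")
        assert all(ts.for_region(r) == 4.9 for r in ALL_REGIONS)

    def test_per_region_requires_all_regions(self):
        with pytest.raises(SpecificationError):
            ThresholdSet(mode="per_region", per_region={Region.CN: 5.0})

    def test_thresholds_must_be_positive(self):
        with pytest.raises(SpecificationError):
            ThresholdSet(central_pct=0.0)


class TestHemisphereDetection:
    def test_lesion_side_detected(self, atlas64, lesioned_volume):
        vol, _ = lesioned_volume
        side, margin = detect_affected_hemisphere(measure_all_regions(vol, atlas64))
        assert side == Hemisphere.LEFT
        assert margin > 0

    def test_symmetric_volume_ties_to_left(self, atlas64):
        vol, _ = simulate_volume(atlas64, PhantomSpec(background_hu_sd=0.0, seed=0))
        side, margin = detect_affected_hemisphere(measure_all_regions(vol, atlas64))
        assert side == Hemisphere.LEFT
        assert margin == pytest.approx(0.0, abs=1e-9)


class TestScoreVolume:
    def test_null_phantom_scores_ten(self, atlas64):
        vol, _ = simulate_volume(atlas64, PhantomSpec(background_hu_sd=0.0, seed=0))
        res = score_volume(vol, atlas64)
        assert res.score == 10
        assert res.affected_regions == ()
        assert not res.hemisphere_overridden

    def test_three_lesions_score_seven(self, atlas64, lesioned_volume):
        vol, truth = lesioned_volume
        res = score_volume(vol, atlas64)
        assert res.affected_hemisphere == Hemisphere.LEFT
        assert set(res.affected_regions) == {Region.CN, Region.INS, Region.M1}
        assert res.score == 7

    def test_subthreshold_drop_not_flagged(self, atlas_hard):
        # hard weights: a 5.0% CN drop measures exactly 5.0 < 5.6
        spec = PhantomSpec(
            background_hu_sd=0.0,
            lesions=(LesionSpec(Region.CN, Hemisphere.LEFT, 5.0),),
            seed=0,
        )
        vol, _ = simulate_volume(atlas_hard, spec)
        res = score_volume(vol, atlas_hard, side_override=Hemisphere.LEFT)
        cn = next(r for r in res.region_results if r.region == Region.CN)
        assert cn.relative_diff_pct == pytest.approx(5.0, abs=1e-9)
        assert not cn.affected
        assert res.score == 10

    def test_side_override_flagged(self, atlas64, lesioned_volume):
        vol, _ = lesioned_volume
        res = score_volume(vol, atlas64, side_override=Hemisphere.RIGHT)
        assert res.affected_hemisphere == Hemisphere.RIGHT
        assert res.hemisphere_overridden

    def test_score_conservation(self, atlas48, noisy_cohort):
        for vol, _ in noisy_cohort[:10]:
            res = score_volume(vol, atlas48)
            assert res.score + len(res.affected_regions) == 10

    def test_mirror_symmetry_swaps_hemisphere_keeps_score(self, atlas48, noisy_cohort):
        for vol, truth in noisy_cohort[:5]:
            if not truth.affected_regions:
                continue
            res = score_volume(vol, atlas48)
            mirrored = CTVolume(np.flip(vol.voxels, axis=0).copy(), vol.voxel_spacing_mm)
            res_m = score_volume(mirrored, atlas48)
            assert res_m.affected_hemisphere == res.affected_hemisphere.opposite
            assert res_m.score == res.score

    def test_contamination_does_not_change_region_mean(self, atlas_hard):
        """Adding voxels below 10 or above 55 HU inside a support never
        moves that region's weighted mean."""
        spec = PhantomSpec(background_hu_sd=0.0, seed=0)
        vol, _ = simulate_volume(atlas_hard, spec)
        base = region_weighted_mean(vol, atlas_hard, Region.LN, Hemisphere.LEFT)
        rng = np.random.default_rng(0)
        support = np.argwhere(atlas_hard.support(Region.LN, Hemisphere.LEFT))
        polluted = vol.voxels.copy()
        for row in support[:: max(1, len(support) // 10)]:
            polluted[tuple(row)] = rng.choice([3.0, 77.0])
        m = region_weighted_mean(
            CTVolume(polluted, vol.voxel_spacing_mm), atlas_hard, Region.LN, Hemisphere.LEFT
        )
        assert m.weighted_mean_hu == pytest.approx(base.weighted_mean_hu, abs=1e-12)

    def test_empty_region_hard_failure_and_tolerant_mode(self, atlas_hard):
        vol, _ = simulate_volume(atlas_hard, PhantomSpec(background_hu_sd=0.0, seed=0))
        voxels = vol.voxels.copy()
        for hemi in Hemisphere:
            voxels[atlas_hard.support(Region.M5, hemi)] = 70.0  # calcified out
        broken = CTVolume(voxels, vol.voxel_spacing_mm)
        with pytest.raises(EmptyRegionError):
            score_volume(broken, atlas_hard)
        res = score_volume(broken, atlas_hard, tolerate_empty=True)
        assert Region.M5 in res.unmeasurable_regions
        assert res.score == 10  # unmeasurable never counts as affected
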