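"""Atlas statistics, abnormality flagging, incidence maps."""

import numpy as np
import pandas as pd
import pytest

from aortaflow.atlas import (
    AbnormalityMap,
    SubjectSample,
    build_atlas,
    compare_patient,
    flag_elevated,
    flag_misdirected,
    incidence_map,
    patient_region_flags,
)


def _sample_like(world, vel_mag=0.5, wss_mag=0.8, axis=2):
    """A constant-magnitude SubjectSample on the shared geometry."""
    _, t_seg, _ = world["template"]
    n_vox = t_seg.n_voxels
    n_pts = len(world["mesh"])
    vel = np.zeros((n_vox, 3))
    vel[:, axis] = vel_mag
    wss = np.zeros((n_pts, 3))
    wss[:, axis] = wss_mag
    return SubjectSample(vel_vec=vel, wss_vec=wss)


class TestBuildAtlas:
    def test_two_subject_hand_arithmetic(self, atlas_world):
        """Magnitudes 0.4 / 0.6 -> mean 0.5, sample SD 0.1414."""
        _, t_seg, _ = atlas_world["template"]
        samples = [
            _sample_like(atlas_world, vel_mag=0.4, wss_mag=0.4),
            _sample_like(atlas_world, vel_mag=0.6, wss_mag=0.6),
        ]
        atl = build_atlas(samples, t_seg, atlas_world["mesh"])
        assert np.allclose(atl.vel_mean_mag, 0.5)
        assert np.allclose(atl.vel_sd_mag, np.sqrt(0.02), atol=1e-12)
        assert np.allclose(atl.wss_sd_mag, np.sqrt(0.02), atol=1e-12)

    def test_identical_subjects_have_zero_sd(self, atlas_world):
        _, t_seg, _ = atlas_world["template"]
        samples = [_sample_like(atlas_world) for _ in range(25)]
        atl = build_atlas(samples, t_seg, atlas_world["mesh"])
        assert np.allclose(atl.vel_sd_mag, 0.0)
        assert np.allclose(atl.vel_mean_mag, 0.5)

    def test_single_subject_rejected(self, atlas_world):
        _, t_seg, _ = atlas_world["template"]
        with pytest.raises(ValueError, match="2 subjects"):
            build_atlas([_sample_like(atlas_world)], t_seg, atlas_world["mesh"])

    def test_low_coverage_locations_undefined(self, atlas_world):
        _, t_seg, _ = atlas_world["template"]
        samples = [_sample_like(atlas_world) for _ in range(10)]
        for s in samples[:5]:  # half the cohort misses the first voxel
            s.vel_vec = s.vel_vec.copy()
            s.vel_vec[0] = np.nan
        atl = build_atlas(samples, t_seg, atlas_world["mesh"])
        assert np.isnan(atl.vel_mean_mag[0])
        assert np.isfinite(atl.vel_mean_mag[1])

    def test_cohort_sd_within_sampling_band(self, atlas_world):
        """Voxelwise SD across 25 phantom subjects sits inside the chi-square
        95% band around the generative between-subject spread."""
        _, t_seg, _ = atlas_world["template"]
        atl = build_atlas(atlas_world["samples"][:25], t_seg, atlas_world["mesh"])
        ok = np.isfinite(atl.vel_mean_mag) & (atl.vel_mean_mag > 0.3)
        # generative: 10% log-normal vmax spread + independent voxel noise
        noise_sd = 0.05
        rel = np.sqrt(np.maximum(atl.vel_sd_mag[ok] ** 2 - noise_sd**2, 1e-12)) \
            / atl.vel_mean_mag[ok]
        frac_in_band = np.mean((rel > 0.10 * 0.71) & (rel < 0.10 * 1.28))
        assert np.median(rel) == pytest.approx(0.10, abs=0.04)
        assert frac_in_band > 0.5


class TestFlagElevated:
    def test_patient_at_atlas_mean_is_never_flagged(self):
        mean = np.full(50, 0.5)
        sd = np.full(50, 0.1)
        flags, evaluated = flag_elevated(mean.copy(), mean, sd)
        assert not flags.any()
        assert evaluated.all()

    def test_single_three_sigma_voxel_flagged(self):
        mean = np.full(50, 0.5)
        sd = np.full(50, 0.1)
        vals = mean.copy()
        vals[7] = 0.5 + 3 * 0.1
        flags, _ = flag_elevated(vals, mean, sd)
        assert flags[7] and flags.sum() == 1

    def test_undefined_atlas_locations_not_flagged(self):
        mean = np.array([0.5, np.nan])
        sd = np.array([0.1, np.nan])
        flags, evaluated = flag_elevated(np.array([10.0, 10.0]), mean, sd)
        assert flags[0] and not flags[1]
        assert evaluated[0] and not evaluated[1]

    def test_flag_count_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        mean = np.full(500, 1.0)
        sd = np.full(500, 0.2)
        vals = rng.normal(1.0, 0.2, 500)
        counts = [flag_elevated(vals, mean, sd, z=z)[0].sum() for z in (1.5, 1.96, 2.5)]
        assert counts[0] >= counts[1] >= counts[2]


class TestFlagMisdirected:
    def _rotated(self, deg):
        ref = np.tile([0.0, 0.0, 1.0], (4, 1))
        a = np.radians(deg)
        vec = np.tile([np.sin(a), 0.0, np.cos(a)], (4, 1))
        return vec, ref

    def test_130_degrees_is_flagged_110_is_not(self):
        for deg, want in ((130.0, True), (110.0, False)):
            vec, ref = self._rotated(deg)
            flags, evaluated = flag_misdirected(vec, ref, angle_deg=120.0)
            assert evaluated.all()
            assert flags.all() == want

    def test_antiparallel_is_flagged(self):
        vec, ref = self._rotated(180.0)
        assert flag_misdirected(vec, ref)[0].all()

    def test_near_zero_vectors_not_evaluated(self):
        ref = np.tile([0.0, 0.0, 1.0], (2, 1))
        vec = np.array([[0.0, 0.0, -0.001], [0.0, 0.0, -1.0]])
        flags, evaluated = flag_misdirected(vec, ref, floor=0.01)
        assert not evaluated[0] and evaluated[1]
        assert not flags[0] and flags[1]

    def test_flag_count_monotone_in_angle(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(300, 3))
        vec = rng.normal(size=(300, 3))
        counts = [
            flag_misdirected(vec, ref, angle_deg=a)[0].sum() for a in (100.0, 120.0, 150.0)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestRegionFlags:
    def _empty_map(self, world):
        _, t_seg, _ = world["template"]
        n_vox, n_pts = t_seg.n_voxels, len(world["mesh"])
        return AbnormalityMap(
            elevated_velocity=np.zeros(n_vox, bool),
            misdirected_velocity=np.zeros(n_vox, bool),
            elevated_wss=np.zeros(n_pts, bool),
            misdirected_wss=np.zeros(n_pts, bool),
            evaluated_velocity=np.ones(n_vox, bool),
            evaluated_wss=np.ones(n_pts, bool),
        )

    def test_single_voxel_sets_only_its_region(self, atlas_world):
        from aortaflow.wss import assign_voxel_regions

        _, t_seg, t_gt = atlas_world["template"]
        vox_regions = assign_voxel_regions(
            t_seg.voxel_centers_m(), atlas_world["mesh"],
            atlas_world["centerline"], t_gt.apex_normal,
        )
        abmap = self._empty_map(atlas_world)
        target = np.flatnonzero(vox_regions == "inner_DAo")[0]
        abmap.elevated_velocity[target] = True
        flags = patient_region_flags(abmap, atlas_world["mesh"], vox_regions)
        assert flags.loc["elevated_velocity", "inner_DAo"] is True or \
            flags.loc["elevated_velocity", "inner_DAo"] == True  # noqa: E712
        row = flags.loc["elevated_velocity"]
        assert row.drop("inner_DAo").astype(bool).sum() == 0
        assert not flags.loc["elevated_wss"].astype(bool).any()

    def test_no_flags_all_false_and_all_flags_all_true(self, atlas_world):
        from aortaflow.wss import assign_voxel_regions

        _, t_seg, t_gt = atlas_world["template"]
        vox_regions = assign_voxel_regions(
            t_seg.voxel_centers_m(), atlas_world["mesh"],
            atlas_world["centerline"], t_gt.apex_normal,
        )
        abmap = self._empty_map(atlas_world)
        flags = patient_region_flags(abmap, atlas_world["mesh"], vox_regions)
        assert not flags.astype(bool).to_numpy().any()
        for name in ("elevated_velocity", "misdirected_velocity"):
            getattr(abmap, name)[:] = True
        for name in ("elevated_wss", "misdirected_wss"):
            getattr(abmap, name)[:] = True
        flags = patient_region_flags(abmap, atlas_world["mesh"], vox_regions)
        assert flags.astype(bool).to_numpy().all()


class TestIncidence:
    def _maps(self, flags_per_patient, n=20):
        out = []
        for fl in flags_per_patient:
            arr = np.asarray(fl, bool)
            out.append(AbnormalityMap(
                elevated_velocity=arr, misdirected_velocity=np.zeros_like(arr),
                elevated_wss=np.zeros(5, bool), misdirected_wss=np.zeros(5, bool),
                evaluated_velocity=np.ones_like(arr), evaluated_wss=np.ones(5, bool),
            ))
        return out

    def test_four_of_ten_gives_forty_percent(self):
        maps = self._maps([[True] * 3] * 4 + [[False] * 3] * 6)
        inc = incidence_map(maps)
        assert np.allclose(inc["elevated_velocity"], 40.0)

    def test_identical_maps_give_zero_or_hundred(self):
        maps = self._maps([[True, False, True]] * 8)
        inc = incidence_map(maps)["elevated_velocity"]
        assert set(np.unique(inc)) <= {0.0, 100.0}

    def test_bernoulli_half_mean_incidence(self):
        rng = np.random.default_rng(5)
        maps = self._maps(list(rng.random((40, 200)) < 0.5))
        inc = incidence_map(maps)["elevated_velocity"]
        assert inc.mean() == pytest.approx(50.0, abs=3.0)

    def test_uncovered_locations_are_nan(self):
        maps = self._maps([[True, False]])
        maps[0].evaluated_velocity = np.array([True, False])
        inc = incidence_map(maps)["elevated_velocity"]
        assert inc[0] == 100.0 and np.isnan(inc[1])


class TestComparePatient:
    def test_patient_equal_to_atlas_mean_is_clean(self, atlas_world):
        _, t_seg, _ = atlas_world["template"]
        samples = [
            _sample_like(atlas_world, vel_mag=m, wss_mag=m) for m in (0.4, 0.5, 0.6)
        ]
        atl = build_atlas(samples, t_seg, atlas_world["mesh"])
        patient = _sample_like(atlas_world, vel_mag=0.5, wss_mag=0.5)
        abmap = compare_patient(atl, patient)
        assert not abmap.elevated_velocity.any()
        assert not abmap.misdirected_velocity.any()
        assert not abmap.elevated_wss.any()
        assert not abmap.misdirected_wss.any()
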