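"""Phantom generator: geometry, symmetry, effects, determinism."""

import dataclasses

import numpy as np
import pytest

from petstage.phantom import (
    CohortSpec,
    PhantomConfig,
    PhantomConfigError,
    ROI_CODES,
    TISSUE_CODES,
    build_template,
    manifest_records,
    perturb_pose,
    place_landmarks,
    simulate_cohort,
    simulate_mri,
    simulate_pet,
)
from conftest import desk_config


class TestBuildTemplate:
    def test_ten_distinct_roi_codes(self, atlas32):
        codes = set(atlas32.codes())
        assert set(ROI_CODES.values()) <= codes
        assert len(set(ROI_CODES.values())) == 10

    def test_contains_all_tissue_codes(self, atlas32):
        assert set(TISSUE_CODES.values()) <= set(atlas32.codes())

    def test_bilateral_pairs_are_mirror_images(self, atlas32):
        data = atlas32.data
        flipped = data[::-1, :, :]
        for base in ("anterior_cingulum", "posterior_cingulum", "inferior_frontal",
                     "precuneus", "lateral_temporal"):
            left = data == ROI_CODES[f"{base}_left"]
            right = data == ROI_CODES[f"{base}_right"]
            assert left.sum() == right.sum() > 0
            np.testing.assert_array_equal(left, (flipped == ROI_CODES[f"{base}_right"]))

    def test_zero_radius_roi_rejected(self):
        cfg = desk_config(32)
        bad_geometry = dict(cfg.roi_geometry)
        center, _ = bad_geometry["precuneus_left"]
        bad_geometry["precuneus_left"] = (center, (0.0, 4.0, 4.0))
        with pytest.raises((PhantomConfigError, ValueError)):
            desk_config(32, roi_geometry=bad_geometry)

    def test_overlapping_rois_rejected_with_names(self):
        cfg = desk_config(32)
        bad_geometry = dict(cfg.roi_geometry)
        # move the left precuneus on top of the left posterior cingulum
        pc_center, pc_radii = bad_geometry["posterior_cingulum_left"]
        bad_geometry["precuneus_left"] = (pc_center, pc_radii)
        with pytest.raises(PhantomConfigError, match="precuneus_left"):
            build_template(desk_config(32, roi_geometry=bad_geometry))


class TestSimulateMri:
    def test_zero_noise_is_piecewise_constant(self, config32, atlas32):
        cfg = dataclasses.replace(config32, noise_sd=0.0)
        mri = simulate_mri(atlas32, cfg, seed=0)
        for tissue, code in TISSUE_CODES.items():
            values = mri.data[atlas32.data == code]
            if values.size:
                assert np.allclose(values, cfg.tissue_means[tissue])

    def test_same_seed_identical(self, config32, atlas32):
        a = simulate_mri(atlas32, config32, seed=5)
        b = simulate_mri(atlas32, config32, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noise_sd_matches_requested(self, atlas32):
        cfg = desk_config(32, noise_sd=3.0)
        mri = simulate_mri(atlas32, cfg, seed=2)
        wm = mri.data[atlas32.data == TISSUE_CODES["WM"]]
        assert wm.size >= 1e3
        assert abs(wm.std() - 3.0) / 3.0 < 0.1


class TestSimulatePet:
    def test_unit_effect_matches_gm(self, atlas32):
        # with a unit effect the ROI interior is indistinguishable from
        # deep GM (voxels away from any tissue boundary)
        from scipy import ndimage

        cfg = desk_config(32, noise_sd=0.0)
        cfg.effect_table[("NC", "FDG")] = 1.0
        pet = simulate_pet(atlas32, "NC", "FDG", "baseline", cfg, seed=0)
        roi = np.isin(atlas32.data, list(ROI_CODES.values()))
        gm_like = (atlas32.data == TISSUE_CODES["GM"]) | roi
        deep_gm = ndimage.binary_erosion(gm_like, iterations=2) & ~roi
        assert deep_gm.sum() > 10
        assert abs(pet.data[roi].mean() - pet.data[deep_gm].mean()) < 0.1 * pet.data[deep_gm].mean()

    def test_effect_ratio_exact_without_smoothing(self):
        cfg = desk_config(64, noise_sd=0.0, smoothing_fwhm=0.0)
        cfg.effect_table[("AD", "FDG")] = 0.7
        cfg.effect_table[("NC", "FDG")] = 1.0
        _, atlas = build_template(cfg)
        pet_ad = simulate_pet(atlas, "AD", "FDG", "baseline", cfg, seed=0)
        pet_nc = simulate_pet(atlas, "NC", "FDG", "baseline", cfg, seed=0)
        for code in ROI_CODES.values():
            roi = atlas.data == code
            ratio = pet_ad.data[roi].mean() / pet_nc.data[roi].mean()
            assert ratio == pytest.approx(0.7, rel=1e-12)

    def test_effect_ratio_diluted_but_present_with_smoothing(self):
        # the 8 mm kernel is comparable to the ROI radii, so the contrast
        # in the eroded interior is diluted towards 1 but stays well below
        from scipy import ndimage

        cfg = desk_config(64, noise_sd=0.0)
        cfg.effect_table[("AD", "FDG")] = 0.7
        cfg.effect_table[("NC", "FDG")] = 1.0
        _, atlas = build_template(cfg)
        pet_ad = simulate_pet(atlas, "AD", "FDG", "baseline", cfg, seed=0)
        pet_nc = simulate_pet(atlas, "NC", "FDG", "baseline", cfg, seed=0)
        ratios = []
        for code in ROI_CODES.values():
            interior = ndimage.binary_erosion(atlas.data == code, iterations=1)
            if interior.sum() >= 3:
                ratios.append(pet_ad.data[interior].mean() / pet_nc.data[interior].mean())
        assert len(ratios) >= 5
        assert all(0.7 <= r < 0.95 for r in ratios)

    def test_smoothing_impulse_response_fwhm(self):
        # a point impulse smoothed at 8 mm FWHM has profile sd = 8/2.355 mm
        from scipy import ndimage

        spacing = 2.0
        fwhm = 8.0
        impulse = np.zeros((33, 33, 33))
        impulse[16, 16, 16] = 1.0
        smoothed = ndimage.gaussian_filter(impulse, sigma=fwhm / 2.355 / spacing)
        x = (np.arange(33) - 16) * spacing
        profile = smoothed[:, 16, 16]
        sd = np.sqrt(np.sum(profile * x**2) / np.sum(profile))
        assert abs(sd - fwhm / 2.355) < 0.1

    def test_missing_effect_entry_raises(self, config32, atlas32):
        cfg = dataclasses.replace(config32, effect_table={("AD", "FDG"): 0.75})
        with pytest.raises(KeyError):
            simulate_pet(atlas32, "NC", "FDG", "baseline", cfg, seed=0)

    def test_effect_ordering_fdg_and_av45(self, atlas32):
        cfg = desk_config(32, noise_sd=0.0, smoothing_fwhm=0.0)
        roi = np.isin(atlas32.data, list(ROI_CODES.values()))
        means = {
            tracer: [
                simulate_pet(atlas32, d, tracer, "baseline", cfg, seed=0).data[roi].mean()
                for d in ("AD", "LMCI", "EMCI", "NC")
            ]
            for tracer in ("FDG", "AV45")
        }
        assert means["FDG"] == sorted(means["FDG"])  # AD < LMCI < EMCI < NC
        assert means["AV45"] == sorted(means["AV45"], reverse=True)

    def test_progression_factor_exact_on_unsmoothed_phantom(self, atlas32):
        cfg = desk_config(32, noise_sd=0.0, smoothing_fwhm=0.0)
        roi = np.isin(atlas32.data, list(ROI_CODES.values()))
        base = simulate_pet(atlas32, "AD", "FDG", "baseline", cfg, seed=0)
        second = simulate_pet(atlas32, "AD", "FDG", "second_visit", cfg, seed=0)
        factor = cfg.progression_table[("AD", "FDG")]
        np.testing.assert_allclose(second.data[roi], base.data[roi] * factor, rtol=1e-12)


class TestPerturbPose:
    def test_zero_ranges_identity(self, config32, atlas32):
        from petstage.phantom import MisalignRanges

        cfg = desk_config(32, noise_sd=0.0,
                          misalign_ranges=MisalignRanges(0.0, 0.0, 0.0, 0.0))
        pet = simulate_pet(atlas32, "NC", "FDG", "baseline", cfg, seed=0)
        moved, truth = perturb_pose(pet, "rigid", cfg, seed=1)
        np.testing.assert_allclose(truth.matrix, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(moved.data, pet.data, atol=1e-9)

    def test_pure_translation_shifts_centroid(self, atlas32):
        from petstage.phantom import MisalignRanges
        from petstage.resampling import resample
        from petstage.transforms import AffineTransform

        cfg = desk_config(32, noise_sd=0.0)
        pet = simulate_pet(atlas32, "NC", "FDG", "baseline", cfg, seed=0)
        t = np.eye(4)
        t[0, 3] = 5.0
        moved = resample(pet, AffineTransform(t), pet)

        def centroid(vol):
            w = vol.data / vol.data.sum()
            idx = np.indices(vol.shape).reshape(3, -1).T
            return vol.voxel_to_world((w.ravel()[:, None] * idx).sum(axis=0))[0]

        shift = centroid(moved) - centroid(pet)
        assert abs(shift[0] - 5.0) < 2.0  # within half a voxel
        assert np.all(np.abs(shift[1:]) < 2.0)

    def test_rigid_pose_has_unit_determinant(self, config32, atlas32):
        pet = simulate_pet(atlas32, "NC", "FDG", "baseline", config32, seed=0)
        _, truth = perturb_pose(pet, "rigid", config32, seed=3)
        assert abs(np.linalg.det(truth.matrix[:3, :3]) - 1.0) < 1e-6


class TestLandmarks:
    def test_one_landmark_per_roi(self, atlas32):
        lms = place_landmarks(atlas32)
        assert len(lms) == 10
        assert set(lms.points) == set(ROI_CODES)

    def test_landmarks_mirror_symmetric(self, atlas32):
        lms = place_landmarks(atlas32)
        half_voxel = float(atlas32.spacing[0]) / 2
        for base in ("anterior_cingulum", "lateral_temporal"):
            left = lms.points[f"{base}_left"]
            right = lms.points[f"{base}_right"]
            assert abs(left[0] + right[0]) < half_voxel
            assert np.all(np.abs(left[1:] - right[1:]) < half_voxel)

    def test_empty_labels_raise(self, config32):
        from petstage.volume import LabelVolume

        empty = LabelVolume(np.zeros((16, 16, 16), dtype=np.int32), config32.affine)
        with pytest.raises(ValueError):
            place_landmarks(empty)


class TestSimulateCohort:
    def test_counts_and_manifest_rows(self, config32, tmp_path):
        spec = CohortSpec(n_per_group={"AD": 2, "EMCI": 2, "LMCI": 2, "NC": 2},
                          tracers=("FDG",), timepoints=("baseline", "second_visit"))
        records = simulate_cohort(spec, config32, seed=0, materialize=False)
        assert len(records) == 8 * 1 * 2
        assert manifest_records(records).shape[0] == 16

    def test_mmse_means_match_parameters(self, config32):
        spec = CohortSpec(n_per_group={"AD": 99, "EMCI": 164, "LMCI": 189, "NC": 208},
                          tracers=("FDG",), timepoints=("baseline",))
        records = simulate_cohort(spec, config32, seed=0, materialize=False)
        df = manifest_records(records)
        expected = {"AD": (22.9, 2.2), "EMCI": (28.5, 1.4), "LMCI": (27.6, 1.8), "NC": (29.1, 1.2)}
        for group, (mean, sd) in expected.items():
            sample = df[df.diagnosis == group].mmse
            n = len(sample)
            assert abs(sample.mean() - mean) < 2 * sd / np.sqrt(n) + 0.05

    def test_same_seed_identical_manifest(self, config32, tmp_path):
        spec = CohortSpec(n_per_group={"AD": 1, "EMCI": 0, "LMCI": 0, "NC": 1}, tracers=("FDG",))
        a = simulate_cohort(spec, config32, seed=4, out_dir=tmp_path / "a")
        b = simulate_cohort(spec, config32, seed=4, out_dir=tmp_path / "b")
        ma = (tmp_path / "a" / "manifest.csv").read_text().replace(str(tmp_path / "a"), "")
        mb = (tmp_path / "b" / "manifest.csv").read_text().replace(str(tmp_path / "b"), "")
        assert ma == mb

    def test_empty_cohort_rejected(self, config32):
        spec = CohortSpec(n_per_group={"AD": 0, "EMCI": 0, "LMCI": 0, "NC": 0})
        with pytest.raises(ValueError):
            simulate_cohort(spec, config32, seed=0, materialize=False)

    def test_materialized_volumes_on_disk(self, config32, tmp_path):
        spec = CohortSpec(n_per_group={"AD": 1, "EMCI": 0, "LMCI": 0, "NC": 0},
                          tracers=("FDG",), timepoints=("baseline",))
        records = simulate_cohort(spec, config32, seed=0, out_dir=tmp_path)
        from petstage.volume import ImageVolume

        rec = records[0]
        pet = ImageVolume.load(rec.pet_path)
        assert pet.shape == tuple(config32.grid_shape)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "landmarks.csv").exists()
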