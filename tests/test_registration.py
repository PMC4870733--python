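"""Automated rotoscoping: templates, scoring, frame and series registration."""

import numpy as np
import pytest

from slicekin.geometry import RigidPose
from slicekin.imaging import FAST_LIKE, T1_LIKE, SliceSpec, apply_blur, render_slice
from slicekin.phantom import (
    PosedSolid,
    generate_trial_series,
    nominal_neutral_poses,
)
from slicekin.registration import (
    extract_displacement_series,
    match_score,
    model_cross_section,
    rotoscope_frame,
    rotoscope_series,
    series_measurements,
)


@pytest.fixture(scope="module")
def clean_translation_series():
    spec = SliceSpec(**T1_LIKE, blur_fwhm=1.0)  # noiseless
    return generate_trial_series("translation_z", [0, 5, 10], 1,
                                 slice_spec=spec, seed=21)


@pytest.fixture(scope="module")
def noisy_translation_series():
    spec = SliceSpec(**T1_LIKE, noise_sigma=0.03, blur_fwhm=1.0)
    return generate_trial_series("translation_z", [0, 5, 10], 1,
                                 slice_spec=spec, seed=22)


class TestTemplate:
    def test_identity_mapping_reproduces_simulator(self, solids,
                                                   identity_mapping,
                                                   sagittal_t1_clean):
        pose_a, pose_b = nominal_neutral_poses()
        sim = render_slice([PosedSolid(solids[0], pose_a)], sagittal_t1_clean)
        tpl = model_cross_section(solids[0], pose_a, sagittal_t1_clean,
                                  identity_mapping)
        assert np.abs(tpl.image - sim).max() < 1e-9
        assert not tpl.empty

    def test_z_shift_translates_template(self, solids, identity_mapping,
                                         sagittal_t1_clean):
        pose_a, _ = nominal_neutral_poses()
        k = 8
        shift = k * sagittal_t1_clean.pixel_size
        t0 = model_cross_section(solids[0], pose_a, sagittal_t1_clean,
                                 identity_mapping)
        t1 = model_cross_section(
            solids[0], RigidPose(np.eye(3), pose_a.translation + [0, 0, shift]),
            sagittal_t1_clean, identity_mapping)
        rolled = np.roll(t0.image, k, axis=1)
        assert np.abs(t1.image[:, k:] - rolled[:, k:]).max() < 1e-9

    def test_missed_slab_flags_empty(self, solids, identity_mapping,
                                     sagittal_t1_clean):
        far = RigidPose(np.eye(3), [300.0, 0.0, 0.0])
        tpl = model_cross_section(solids[0], far, sagittal_t1_clean,
                                  identity_mapping)
        assert tpl.empty and tpl.image.max() == 0.0


class TestMatchScore:
    def test_self_score_is_one(self, solids, identity_mapping, sagittal_t1_clean):
        pose_a, _ = nominal_neutral_poses()
        tpl = model_cross_section(solids[0], pose_a, sagittal_t1_clean,
                                  identity_mapping).image
        assert match_score(tpl, tpl) == pytest.approx(1.0)
        assert match_score(tpl, -tpl) == pytest.approx(-1.0)

    def test_truth_pose_scores_high_on_noiseless_image(
            self, solids, identity_mapping, clean_translation_series):
        frame = clean_translation_series.frames[0]
        spec = frame.specs[0]
        tpl = np.maximum(
            model_cross_section(solids[0], frame.pose_a, spec, identity_mapping).image,
            model_cross_section(solids[1], frame.pose_b, spec, identity_mapping).image)
        assert match_score(apply_blur(tpl, spec), frame.images[0]) > 0.99

    def test_constant_inputs_flagged_zero(self):
        with pytest.warns(UserWarning):
            assert match_score(np.zeros((8, 8)), np.ones((8, 8))) == 0.0


class TestFrameRegistration:
    def test_init_at_truth_stays_at_truth(self, solids, identity_mapping,
                                          clean_translation_series):
        frame = clean_translation_series.frames[1]
        res = rotoscope_frame(frame.images, frame.specs, solids,
                              (frame.pose_a, frame.pose_b), "tz",
                              identity_mapping, restarts=1,
                              rng=np.random.default_rng(0))
        err = res.pose_b.translation[2] - frame.pose_b.translation[2]
        assert abs(err) < 1e-3
        assert not res.failed

    def test_offset_init_recovers_translation(self, solids, identity_mapping,
                                              clean_translation_series):
        frame = clean_translation_series.frames[1]
        init_b = RigidPose(np.eye(3), frame.pose_b.translation + [0, 0, 3.0])
        res = rotoscope_frame(frame.images, frame.specs, solids,
                              (frame.pose_a, init_b), "tz", identity_mapping,
                              restarts=2, rng=np.random.default_rng(0))
        assert abs(res.pose_b.translation[2] - frame.pose_b.translation[2]) < 0.1

    def test_rotation_recovered_within_half_degree(self, solids, identity_mapping):
        spec = SliceSpec(**T1_LIKE, blur_fwhm=1.0)
        series = generate_trial_series("rotation_x", [0, 20], 1,
                                       slice_spec=spec, seed=23, jitter=0.0)
        frame = series.frames[1]  # 20-degree frame
        from scipy.spatial.transform import Rotation
        init_rot = Rotation.from_euler("x", 15.0, degrees=True).as_matrix()
        init_b = RigidPose(init_rot, frame.pose_b.translation)
        res = rotoscope_frame(frame.images, frame.specs, solids,
                              (frame.pose_a, init_b), "rx", identity_mapping,
                              restarts=2, rng=np.random.default_rng(0))
        rec = Rotation.from_matrix(
            res.pose_b.rotation @ frame.pose_a.rotation.T).as_euler(
                "xyz", degrees=True)[0]
        assert abs(rec - 20.0) < 0.5

    def test_unknown_dof_mask_rejected(self, solids, identity_mapping,
                                       clean_translation_series):
        frame = clean_translation_series.frames[0]
        with pytest.raises(ValueError):
            rotoscope_frame(frame.images, frame.specs, solids,
                            (frame.pose_a, frame.pose_b), "ty",
                            identity_mapping)


class TestSeriesRegistration:
    def test_noiseless_series_within_optimizer_tolerance(
            self, solids, identity_mapping, clean_translation_series):
        res = rotoscope_series(clean_translation_series, solids,
                               identity_mapping, restarts=2, seed=5)
        meas = series_measurements(
            extract_displacement_series(res), "translation_z")
        truth = clean_translation_series.ground_truth_displacements()
        assert np.abs(meas - truth).max() <= 0.05
        assert res.failures == []

    def test_noisy_series_subvoxel(self, solids, identity_mapping,
                                   noisy_translation_series):
        res = rotoscope_series(noisy_translation_series, solids,
                               identity_mapping, restarts=2, seed=5)
        meas = series_measurements(
            extract_displacement_series(res), "translation_z")
        truth = noisy_translation_series.ground_truth_displacements()
        assert np.abs(meas - truth).max() <= 0.5

    def test_score_decreases_away_from_optimum(self, solids, identity_mapping,
                                               clean_translation_series):
        res = rotoscope_series(clean_translation_series, solids,
                               identity_mapping, restarts=2, seed=5)
        frame = clean_translation_series.frames[1]
        reg = res.frames[1]
        static = model_cross_section(solids[0], reg.pose_a, frame.specs[0],
                                     identity_mapping).image
        scores = []
        for dz in [0.0, 0.5, 1.0, 2.0, 5.0]:
            pose = RigidPose(reg.pose_b.rotation,
                             reg.pose_b.translation + [0, 0, dz])
            tpl = np.maximum(
                static,
                model_cross_section(solids[1], pose, frame.specs[0],
                                    identity_mapping).image)
            scores.append(match_score(apply_blur(tpl, frame.specs[0]),
                                      frame.images[0]))
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_injected_poses_reproduce_truth_exactly(self, solids,
                                                    identity_mapping,
                                                    clean_translation_series):
        override = [(f.pose_a, f.pose_b)
                    for f in clean_translation_series.frames]
        res = rotoscope_series(clean_translation_series, solids,
                               identity_mapping, poses_override=override)
        meas = series_measurements(
            extract_displacement_series(res), "translation_z")
        truth = clean_translation_series.ground_truth_displacements()
        assert meas == pytest.approx(truth, abs=1e-9)

    def test_session2_reuses_session1_axes(self, solids, identity_mapping,
                                           noisy_translation_series):
        res1 = rotoscope_series(noisy_translation_series, solids,
                                identity_mapping, restarts=1, seed=5)
        res2 = rotoscope_series(noisy_translation_series, solids,
                                identity_mapping, restarts=1, seed=6,
                                axes=res1.axes)
        assert res2.axes.origin == pytest.approx(res1.axes.origin)


class TestBiplanar:
    def test_biplanar_recovers_both_planes(self, solids, identity_mapping):
        spec = SliceSpec(**FAST_LIKE, noise_sigma=0.03, blur_fwhm=1.0)
        series = generate_trial_series("biplanar", [0, 10], 1,
                                       slice_spec=spec, seed=24)
        res = rotoscope_series(series, solids, identity_mapping, restarts=2,
                               seed=5)
        meas = series_measurements(
            extract_displacement_series(res), "biplanar")
        truth = series.ground_truth_displacements()
        assert np.abs(meas - truth).max() <= 0.7

    def test_orthogonal_view_does_not_hurt_x_recovery(self, solids,
                                                      identity_mapping):
        # x translation is out-of-plane for the sagittal slice alone; the
        # added axial view must not increase the x-plane recovery error
        spec = SliceSpec(**FAST_LIKE, noise_sigma=0.03, blur_fwhm=1.0)
        series = generate_trial_series("biplanar", [0, 10], 1,
                                       slice_spec=spec, seed=25)
        truth = series.ground_truth_displacements()

        res_bi = rotoscope_series(series, solids, identity_mapping,
                                  restarts=2, seed=5)
        err_bi = np.abs(series_measurements(
            extract_displacement_series(res_bi), "biplanar")[:, 1] - truth[:, 1])

        single = type(series)(
            "biplanar",
            tuple(type(f)(f.index, f.nominal, f.images[:1], f.specs[:1],
                          f.pose_a, f.pose_b) for f in series.frames),
            series.seed, series.jitter)
        res_sp = rotoscope_series(single, solids, identity_mapping,
                                  restarts=2, seed=5)
        err_sp = np.abs(series_measurements(
            extract_displacement_series(res_sp), "biplanar")[:, 1] - truth[:, 1])
        assert err_bi.mean() <= err_sp.mean() + 1e-9
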