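"""Chart generator: rendering geometry, ground truth, and degradations."""

import math

import numpy as np
import pytest

from lapqc import chartgen as cg
from lapqc.profile import LineSegment, detect_extrema, sample_profile


class TestUsafGeometry:
    @pytest.mark.parametrize(
        "group, element, lp_mm, width_um",
        [
            # cross-checked against the published USAF-1951 chart table
            (2, 3, 5.04, 99.21),
            (0, 1, 1.00, 500.00),
            (2, 6, 7.13, 70.15),
            (-2, 2, 0.281, 1781.80),
            (7, 6, 228.07, 2.19),
        ],
    )
    def test_frequency_and_line_width_match_published_table(
        self, group, element, lp_mm, width_um
    ):
        assert cg.usaf_frequency_lp_mm(group, element) == pytest.approx(lp_mm, rel=2e-3)
        assert cg.usaf_line_width_um(group, element) == pytest.approx(width_um, rel=2e-3)

    def test_bar_spacing_on_rendered_chart(self, usaf_group1):
        _, img, truth = usaf_group1
        for el in truth.usaf_elements:
            centers = np.array(el.bar_center_cols)
            period_px = 36.0 / el.frequency_lp_mm
            # dark bars sit one line pair apart
            assert np.allclose(np.diff(centers), period_px, atol=1e-9)

    def test_rendered_levels(self, usaf_group1):
        _, img, truth = usaf_group1
        row = img.shape[0] // 2
        for el in truth.usaf_elements:
            cols = [int(round(c)) for c in el.bar_center_cols]
            assert all(img[row, c] <= 1 for c in cols)

    def test_nyquist_violation_names_offender(self):
        with pytest.raises(ValueError, match=r"group 7, element 6"):
            cg.usaf_chart(group=7, elements=[6], px_per_mm=40.0)

    def test_duplicate_elements_rejected(self):
        els = (cg.UsafElementSpec(1, 1), cg.UsafElementSpec(1, 1))
        with pytest.raises(ValueError, match="unique"):
            cg.UsafChartSpec(
                width_px=400, height_px=100, px_per_mm=30.0, elements=els
            )

    def test_render_is_deterministic(self, usaf_group1):
        spec, img, _ = usaf_group1
        img2, _ = cg.render_chart(spec)
        assert np.array_equal(img, img2)


class TestGridAndLandmarks:
    def test_identity_landmarks_without_distortion(self, grid5):
        _, _, truth = grid5
        assert truth.landmarks_post == truth.landmarks_pre

    def test_landmarks_sit_on_dark_lines(self, grid5):
        _, img, truth = grid5
        for r, c in truth.landmarks_pre.values():
            assert img[int(round(r)), int(round(c))] <= 1

    def test_forward_map_matches_hand_computation(self, grid5):
        _, img, truth = grid5
        k1 = -0.05
        _, t2 = cg.apply_degradation(img, truth, cg.DegradationSpec(k1=k1))
        h, w = img.shape
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        rnorm = math.hypot(*center)
        for name, pre in truth.landmarks_pre.items():
            d = (np.array(pre) - center) / rnorm
            expected = center + d * (1.0 + k1 * float(d @ d)) * rnorm
            assert t2.landmarks_post[name] == pytest.approx(tuple(expected), abs=1e-9)

    @pytest.mark.parametrize("k1, toward_center", [(-0.06, True), (0.06, False)])
    def test_radial_displacement_direction(self, grid5, k1, toward_center):
        _, img, truth = grid5
        _, t2 = cg.apply_degradation(img, truth, cg.DegradationSpec(k1=k1))
        h, w = img.shape
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        for name, pre in truth.landmarks_pre.items():
            r_pre = np.linalg.norm(np.array(pre) - center)
            r_post = np.linalg.norm(np.array(t2.landmarks_post[name]) - center)
            assert bool(r_post < r_pre) == toward_center

    def test_landmark_mapped_outside_frame_errors(self, grid5):
        _, img, truth = grid5
        with pytest.raises(ValueError, match="outside the frame"):
            cg.apply_degradation(img, truth, cg.DegradationSpec(k1=0.9))


class TestDegradations:
    def test_identity_degradation_is_bitwise_noop(self, usaf_group1):
        _, img, truth = usaf_group1
        out, t2 = cg.apply_degradation(img, truth, cg.DegradationSpec())
        assert np.array_equal(out, img)
        assert t2.degradation is not None

    def test_seeded_noise_is_reproducible(self, usaf_group1):
        _, img, truth = usaf_group1
        deg = cg.DegradationSpec(noise_sigma=4.0, seed=11)
        a, _ = cg.apply_degradation(img, truth, deg)
        b, _ = cg.apply_degradation(img, truth, deg)
        c, _ = cg.apply_degradation(
            img, truth, cg.DegradationSpec(noise_sigma=4.0, seed=12)
        )
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_blur_conserves_mean_intensity(self, usaf_group1):
        _, img, truth = usaf_group1
        pad = 16
        padded = np.pad(img, pad, mode="edge")
        out, _ = cg.apply_degradation(padded, truth, cg.DegradationSpec(blur_sigma_px=3.0))
        inner = out[pad:-pad, pad:-pad]
        assert abs(float(inner.mean()) - float(img.mean())) <= 1.0

    def test_lab_offset_requires_rgb(self, usaf_group1):
        _, img, truth = usaf_group1
        with pytest.raises(ValueError, match="RGB"):
            cg.apply_degradation(img, truth, cg.DegradationSpec(lab_offset=(5, 0, 0)))

    def test_lab_offset_updates_effective_patch_labs(self, colorchecker24):
        _, img, truth = colorchecker24
        _, t2 = cg.apply_degradation(img, truth, cg.DegradationSpec(lab_offset=(2.0, -1.0, 3.0)))
        for p_in, p_out in zip(truth.patches, t2.patches):
            assert p_out.lab_effective == pytest.approx(
                (p_in.lab_ref[0] + 2.0, p_in.lab_ref[1] - 1.0, p_in.lab_ref[2] + 3.0)
            )
        # original truth untouched
        assert truth.patches[0].lab_effective == truth.patches[0].lab_ref

    def test_blur_and_gradient_are_mutually_exclusive(self):
        with pytest.raises(ValueError):
            cg.DegradationSpec(blur_sigma_px=1.0, blur_gradient=(0.0, 2.0))


class TestDofLadder:
    def test_ten_mm_ladder_has_fifty_pairs(self, dof_ladder10):
        spec, img, truth = dof_ladder10
        assert truth.dof.n_pairs == 50
        line = LineSegment((0.0, truth.dof.profile_col), (img.shape[0] - 1.0, truth.dof.profile_col))
        ext = detect_extrema(sample_profile(img, line))
        assert len(ext.troughs) == 50  # one dark bar per line pair

    def test_undegraded_ladder_has_no_failure(self, dof_ladder10):
        _, _, truth = dof_ladder10
        assert truth.dof.failure_mm is None

    def test_contrast_ramp_failure_position_closed_form(self):
        # contrast falls linearly 255 -> 5 over 10 mm; the half-initial
        # crossing of c(x) = 255 - 25x against c(0.2)/2 = 125 sits at 5.2 mm
        spec = cg.dof_ladder_chart(length_mm=10.0, px_per_mm=40.0, end_levels=(105, 100))
        _, truth = cg.render_chart(spec)
        assert truth.dof.failure_mm == pytest.approx(5.2, abs=0.25)

    def test_gradient_blur_failure_matches_target(self):
        spec = cg.dof_ladder_chart(length_mm=6.0, px_per_mm=40.0)
        deg = cg.solve_blur_gradient_for_failure(spec, 4.0)
        img, truth = cg.render_chart(spec)
        _, t2 = cg.apply_degradation(img, truth, deg)
        assert t2.dof.failure_mm == pytest.approx(4.0, abs=1e-3)


class TestGroundTruthSerialization:
    @pytest.mark.parametrize("fixture", ["usaf_group1", "grid5", "colorchecker24", "dof_ladder10"])
    def test_json_round_trip(self, fixture, request):
        _, _, truth = request.getfixturevalue(fixture)
        restored = cg.GroundTruth.from_json(truth.to_json())
        assert restored.to_json() == truth.to_json()
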