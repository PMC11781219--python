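"""Color accuracy: sRGB->CIELAB conversion, dE*ab / dC*ab, patch extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lapqc import chartgen as cg
from lapqc import colorimetry as cm
from lapqc.colorimetry import LabColor, delta_c_ab, delta_e_ab, srgb_to_lab


def _hand_srgb_to_lab(rgb):
    """Independent oracle: the published sRGB (IEC 61966-2-1) -> XYZ (D65)
    -> CIELAB equations, written out by hand."""
    c = np.asarray(rgb, dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [
            [0.4124564, 0.3575761, 0.1804375],
            [0.2126729, 0.7151522, 0.0721750],
            [0.0193339, 0.1191920, 0.9503041],
        ]
    )
    X, Y, Z = M @ lin
    wn = (0.95047, 1.0, 1.08883)  # D65, 2 degree observer

    def f(t):
        return t ** (1 / 3) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29

    fx, fy, fz = f(X / wn[0]), f(Y / wn[1]), f(Z / wn[2])
    return 116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)


class TestSrgbToLab:
    def test_white_maps_to_reference_white(self):
        lab = srgb_to_lab((255, 255, 255))
        assert lab.L == pytest.approx(100.0, abs=1e-6)
        assert abs(lab.a) < 0.01 and abs(lab.b) < 0.01

    def test_black_maps_to_zero(self):
        lab = srgb_to_lab((0, 0, 0))
        assert (lab.L, lab.a, lab.b) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_mid_gray_is_neutral_L50(self):
        lab = srgb_to_lab((119, 119, 119))
        assert lab.L == pytest.approx(50.0, abs=0.2)
        assert abs(lab.a) < 0.01 and abs(lab.b) < 0.01

    @pytest.mark.parametrize("rgb", [(12, 34, 56), (200, 150, 30), (255, 0, 128), (80, 80, 90)])
    def test_matches_hand_computed_oracle(self, rgb):
        lab = srgb_to_lab(rgb)
        L, a, b = _hand_srgb_to_lab(rgb)
        assert (lab.L, lab.a, lab.b) == pytest.approx((L, a, b), abs=0.01)

    def test_lab_color_validates_luminance_range(self):
        with pytest.raises(ValueError, match="L\\*"):
            LabColor(120.0, 0.0, 0.0)


class TestDeltaFormulas:
    def test_identity_is_zero(self):
        m = LabColor(50, 10, -10)
        assert delta_e_ab(m, m) == 0.0
        assert delta_c_ab(m, m) == 0.0

    def test_pythagorean_closed_forms(self):
        r = LabColor(50, 0, 0)
        assert delta_e_ab(LabColor(53, 4, 0), r) == pytest.approx(5.0, abs=1e-9)
        assert delta_e_ab(LabColor(51, 2, 2), r) == pytest.approx(3.0, abs=1e-9)
        assert delta_c_ab(LabColor(90, 3, 4), r) == pytest.approx(5.0, abs=1e-9)

    def test_pure_luminance_difference(self):
        r = LabColor(40, 5, 5)
        m = LabColor(50, 5, 5)
        assert delta_e_ab(m, r) == pytest.approx(10.0, abs=1e-12)
        assert delta_c_ab(m, r) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=3,
            max_size=3,
        )
    )
    def test_triangle_inequality(self, triple):
        m, q, r = (LabColor(*t) for t in triple)
        assert delta_e_ab(m, r) <= delta_e_ab(m, q) + delta_e_ab(q, r) + 1e-9


class TestPatchExtraction:
    def test_synthetic_chart_round_trips_rendered_colors(self, colorchecker24):
        _, img, truth = colorchecker24
        layout = cm.layout_from_truth(truth)
        means = cm.extract_patches(img, layout)
        for mean, p in zip(means, truth.patches):
            assert np.allclose(mean, p.rgb_rendered, atol=1.0)

    def test_inner_fraction_keeps_border_bleed_out(self):
        img = np.full((40, 40, 3), 200, dtype=np.uint8)
        img[10, 10:30] = 0
        img[29, 10:30] = 0
        img[10:30, 10] = 0
        img[10:30, 29] = 0  # 1-px dark border inside the ROI
        roi = (10, 10, 30, 30)
        inner = cm.extract_patches(img, cm.PatchLayout((roi,), inner_fraction=0.5))[0]
        full = cm.extract_patches(img, cm.PatchLayout((roi,), inner_fraction=1.0))[0]
        assert inner == pytest.approx((200.0,) * 3)
        assert all(f < i for f, i in zip(full, inner))

    def test_uniform_image_gives_identical_patches(self):
        img = np.full((60, 60, 3), 99, dtype=np.uint8)
        layout = cm.PatchLayout(((0, 0, 20, 20), (30, 30, 50, 50)))
        a, b = cm.extract_patches(img, layout)
        assert a == b == (99.0, 99.0, 99.0)

    def test_roi_outside_image_names_patch(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="patch 1"):
            cm.extract_patches(
                img, cm.PatchLayout(((0, 0, 10, 10), (15, 15, 25, 25)))
            )


class TestComparison:
    def test_zero_degradation_mean_error_is_quantization_only(
        self, colorchecker24, classic24_reference
    ):
        _, img, truth = colorchecker24
        res = cm.compare_to_reference(
            img,
            cm.layout_from_truth(truth),
            cm.as_rendered_reference(classic24_reference),
        )
        assert res.mean_delta_e <= 1.0
        assert res.mean_delta_c <= res.mean_delta_e + 1e-12

    @pytest.mark.parametrize("offset", [(5.0, 0.0, 0.0), (3.0, 4.0, 0.0)])
    def test_uniform_lab_offset_shifts_mean_by_its_norm(
        self, colorchecker24, classic24_reference, offset
    ):
        _, img, truth = colorchecker24
        shifted, _ = cg.apply_degradation(img, truth, cg.DegradationSpec(lab_offset=offset))
        res = cm.compare_to_reference(
            shifted,
            cm.layout_from_truth(truth),
            cm.as_rendered_reference(classic24_reference),
        )
        assert res.mean_delta_e == pytest.approx(np.linalg.norm(offset), abs=0.5)

    def test_delta_e_dominates_delta_c_per_patch(self, colorchecker24, classic24_reference):
        _, img, truth = colorchecker24
        shifted, _ = cg.apply_degradation(
            img, truth, cg.DegradationSpec(lab_offset=(2.0, -3.0, 1.0))
        )
        res = cm.compare_to_reference(
            shifted, cm.layout_from_truth(truth), classic24_reference
        )
        for p in res.patches:
            assert p.delta_e >= p.delta_c >= 0.0

    def test_white_balance_patches_excluded_from_color_mean(self):
        ref = pd.DataFrame(
            {
                "patch_id": ["c1", "c2", "wb"],
                "role": ["color", "color", "white_balance"],
                "L": [50.0, 50.0, 90.0],
                "a": [0.0, 0.0, 0.0],
                "b": [0.0, 0.0, 0.0],
            }
        )
        img = np.zeros((10, 30, 3), dtype=np.uint8)
        c = cm.lab_to_srgb(LabColor(50, 0, 0))
        img[:, 0:10] = c
        img[:, 10:20] = c
        img[:, 20:30] = 0  # wildly wrong white-balance square
        layout = cm.PatchLayout(((0, 0, 10, 10), (0, 10, 10, 20), (0, 20, 10, 30)))
        res = cm.compare_to_reference(img, layout, ref)
        assert res.mean_delta_e <= 0.2  # untouched by the broken wb patch
        assert res.mean_delta_e_wb == pytest.approx(90.0, abs=1.0)

    def test_mean_is_arithmetic_over_color_patches(self):
        ref = pd.DataFrame(
            {
                "patch_id": ["c1", "c2"],
                "role": ["color", "color"],
                "L": [53.0, 55.0],  # dE 3 and 5 against rendered L=50 gray
                "a": [0.0, 0.0],
                "b": [0.0, 0.0],
            }
        )
        img = np.zeros((10, 20, 3), dtype=np.uint8)
        img[:, :] = cm.lab_to_srgb(LabColor(50, 0, 0))
        layout = cm.PatchLayout(((0, 0, 10, 10), (0, 10, 10, 20)))
        res = cm.compare_to_reference(img, layout, ref)
        assert res.mean_delta_e == pytest.approx(4.0, abs=0.1)
        assert res.mean_delta_e_wb is None

    def test_mismatched_reference_length_rejected(self, colorchecker24, classic24_reference):
        _, img, truth = colorchecker24
        layout = cm.PatchLayout(tuple(p.roi for p in truth.patches[:10]))
        with pytest.raises(ValueError, match="10"):
            cm.compare_to_reference(img, layout, classic24_reference)


class TestSwatchesAndPresets:
    def test_swatch_halves_show_reference_and_measured(self):
        ref = LabColor(60, 20, 20)
        mea = LabColor(40, -20, 5)
        res = cm.ColorDiffResult(
            patches=[
                cm.PatchDiff("p", "color", (0, 0, 0), mea, ref, delta_e_ab(mea, ref), delta_c_ab(mea, ref))
            ],
            mean_delta_e=1.0,
            mean_delta_c=1.0,
            mean_delta_e_wb=None,
            mean_delta_c_wb=None,
        )
        img = cm.swatch_image(res, tile_px=20, cols=1)
        assert img.shape == (20, 20, 3)
        assert tuple(img[10, 4]) == cm.lab_to_srgb(ref)
        assert tuple(img[10, 15]) == cm.lab_to_srgb(mea)

    @pytest.mark.parametrize("name", cm.REFERENCE_PRESETS)
    def test_bundled_presets_load_and_validate(self, name):
        df = cm.load_reference_preset(name)
        assert len(df) == 24
        assert (df["role"] == "color").sum() == 18

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            cm.load_reference_preset("nope")
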