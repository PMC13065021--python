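"""Midline, straightening, rotational-symmetry volumetry, fluorescence."""

import numpy as np
import pytest
from scipy.ndimage import rotate as nd_rotate
from skimage.draw import disk

from wormgrowth import morphometry as mm
from wormgrowth import synthetic as syn


class TestExtractMidline:
    def test_rectangle_midline_length(self):
        mask = np.zeros((50, 140), bool)
        mask[20:30, 10:110] = True
        ml = mm.extract_midline(mask)
        assert ml.length == pytest.approx(100, abs=2)
        assert np.all(np.diff(ml.arc_length) > 0)

    def test_disk_fails_no_elongated_axis(self):
        mask = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 15)
        mask[rr, cc] = True
        with pytest.raises(mm.StraighteningError):
            mm.extract_midline(mask)

    def test_rotation_invariant_length(self, noiseless_render):
        _, mask, _ = noiseless_render
        ml = mm.extract_midline(mask)
        mask90 = np.rot90(mask).copy()
        ml90 = mm.extract_midline(mask90)
        assert ml90.length == pytest.approx(ml.length, rel=0.01)

    def test_empty_and_multicomponent_rejected(self):
        with pytest.raises(mm.StraighteningError):
            mm.extract_midline(np.zeros((10, 10), bool))
        two = np.zeros((60, 120), bool)
        two[10:18, 5:50] = True
        two[40:48, 60:110] = True
        with pytest.raises(mm.StraighteningError):
            mm.extract_midline(two)


class TestStraighten:
    def test_straight_worm_intensity_conserved(self):
        img, mask = syn.render_cylinder(5.0, 100, intensity=80.0)
        ml = mm.extract_midline(mask)
        st = mm.straighten(img.astype(float), mask, ml)
        total_in = img.astype(float).sum()  # zero background: all signal
        total_out = st.image.sum()
        assert total_out == pytest.approx(total_in, rel=0.02)

    def test_curved_worm_length_matches_truth(self, noiseless_render):
        img, mask, midline_true = noiseless_render
        ml = mm.extract_midline(mask)
        assert ml.length == pytest.approx(len(midline_true), rel=0.03)

    def test_constant_radius_width_profile_flat(self):
        img, mask = syn.render_cylinder(5.0, 100)
        ml = mm.extract_midline(mask)
        st = mm.straighten(img.astype(float), mask, ml)
        n = st.width.size
        core = st.width[int(0.1 * n): int(0.9 * n)]
        assert core.max() - core.min() <= 1.0


class TestEstimateVolume:
    def test_cylinder_closed_form(self):
        # constant width 10 px over 100 rows at 1 µm/px: V = pi*25*100
        st = mm.StraightenedWorm(
            image=np.zeros((100, 21)),
            mask_rows=np.zeros((100, 21), bool),
            width=np.full(100, 10.0),
            length=100.0,
        )
        assert mm.estimate_volume(st, 1.0) == pytest.approx(np.pi * 25 * 100, rel=1e-6)

    def test_rendered_cylinder_within_three_percent(self):
        img, mask = syn.render_cylinder(5.0, 100)
        ml = mm.extract_midline(mask)
        st = mm.straighten(img.astype(float), mask, ml)
        assert mm.estimate_volume(st, 1.0) == pytest.approx(np.pi * 25 * 100, rel=0.03)

    def test_curved_renders_match_generator_truth(self):
        for s in range(6):
            rng = np.random.default_rng(s)
            img, mask, _ = syn.render_worm_frame(
                1.2e5, 100.0, (240, 240), 2.5, 20.0, 0.0, rng, blur_sigma=0.0
            )
            ml = mm.extract_midline(mask)
            st = mm.straighten(img.astype(float), mask, ml)
            assert mm.estimate_volume(st, 2.5) == pytest.approx(1.2e5, rel=0.03)

    def test_zero_width_gives_zero_volume(self):
        st = mm.StraightenedWorm(
            image=np.zeros((10, 5)),
            mask_rows=np.zeros((10, 5), bool),
            width=np.zeros(10),
            length=10.0,
        )
        assert mm.estimate_volume(st) == 0.0

    def test_empty_profile_missing(self):
        st = mm.StraightenedWorm(
            image=np.zeros((0, 5)),
            mask_rows=np.zeros((0, 5), bool),
            width=np.zeros(0),
            length=0.0,
        )
        assert np.isnan(mm.estimate_volume(st))

    def test_rotation_pose_invariance(self, noiseless_render):
        img, mask, _ = noiseless_render
        vols = []
        for ang in range(0, 360, 45):
            m2 = nd_rotate(mask.astype(float), ang, reshape=False, order=1) > 0.5
            i2 = nd_rotate(img, ang, reshape=False, order=1)
            ml = mm.extract_midline(m2)
            st = mm.straighten(i2, m2, ml)
            vols.append(mm.estimate_volume(st, 2.5))
        vols = np.array(vols)
        assert vols.std() / vols.mean() < 0.02


class TestBackgroundAndFluorescence:
    def test_background_exact_on_clean_render(self, noiseless_render):
        img, mask, _ = noiseless_render
        assert mm.estimate_background(img, mask) == pytest.approx(20.0, abs=1e-9)

    def test_background_under_noise_close_to_truth(self):
        rng = np.random.default_rng(0)
        img = np.full((200, 200), 50.0) + rng.normal(0, 5.0, (200, 200))
        mask = np.zeros((200, 200), bool)
        mask[80:120, 80:120] = True
        img[mask] += 300
        n_outside = (~mask).sum()
        assert mm.estimate_background(img, mask) == pytest.approx(
            50.0, abs=3 * 5.0 / np.sqrt(n_outside) + 0.5
        )

    def test_background_ignores_pixels_inside_mask(self, noiseless_render):
        img, mask, _ = noiseless_render
        img2 = img.copy()
        img2[mask] *= 10
        assert mm.estimate_background(img, mask) == mm.estimate_background(img2, mask)

    def test_mask_covering_frame_rejected(self):
        with pytest.raises(ValueError):
            mm.estimate_background(np.ones((30, 30)), np.ones((30, 30), bool))

    def test_uniform_worm_concentration_exact(self):
        img = np.full((60, 60), 5.0)
        mask = np.zeros((60, 60), bool)
        mask[20:40, 20:40] = True
        img[mask] = 42.0
        f = mm.measure_fluorescence(img, mask, background=5.0)
        assert f.concentration == pytest.approx(37.0, abs=1e-12)
        assert f.area == 400

    def test_concentration_scale_equivariance(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 50, (50, 50))
        mask = np.zeros((50, 50), bool)
        mask[10:30, 15:35] = True
        f1 = mm.measure_fluorescence(img, mask, 12.0)
        f2 = mm.measure_fluorescence(3.0 * img, mask, 36.0)
        assert f2.concentration == pytest.approx(3.0 * f1.concentration, rel=1e-12)

    def test_dimming_halves_concentration(self, noiseless_render):
        img, mask, _ = noiseless_render
        bg = mm.estimate_background(img, mask)
        c1 = mm.measure_fluorescence(img, mask, bg).concentration
        dim = 0.5 * img
        c2 = mm.measure_fluorescence(dim, mask, mm.estimate_background(dim, mask)).concentration
        assert c2 == pytest.approx(0.5 * c1, rel=0.01)

    def test_empty_mask_missing(self):
        f = mm.measure_fluorescence(np.ones((10, 10)), np.zeros((10, 10), bool), 0.0)
        assert np.isnan(f.concentration)


class TestQuantifyRoi:
    def test_no_exclusion_matches_measure_fluorescence(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 10, (40, 40))
        roi = np.zeros((40, 40), bool)
        roi[5:20, 5:20] = True
        c = mm.quantify_roi(img, roi, None, background=1.0)
        assert c == pytest.approx(
            mm.measure_fluorescence(img, roi, 1.0).concentration, rel=1e-12
        )

    def test_uniform_roi(self):
        img = np.full((20, 20), 9.0)
        roi = np.ones((20, 20), bool)
        assert mm.quantify_roi(img, roi, background=2.0) == pytest.approx(7.0)

    def test_excluding_bright_subregion_lowers_value(self):
        img = np.full((30, 30), 10.0)
        roi = np.zeros((30, 30), bool)
        roi[5:25, 5:25] = True
        bright = np.zeros_like(roi)
        bright[10:15, 10:15] = True
        img[bright] = 100.0
        with_nucleus = mm.quantify_roi(img, roi, None, 0.0)
        without = mm.quantify_roi(img, roi, bright, 0.0)
        assert without < with_nucleus
        assert without == pytest.approx(10.0)

    def test_empty_effective_roi_missing(self):
        roi = np.zeros((10, 10), bool)
        roi[2, 2] = True
        assert np.isnan(mm.quantify_roi(np.ones((10, 10)), roi, roi, 0.0))
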