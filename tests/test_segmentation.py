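"""Edge detection, contour closing, mask extraction and frame QC."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import circle_perimeter, disk

from wormgrowth import segmentation as seg
from wormgrowth import synthetic as syn


class TestDetectEdges:
    def test_constant_image_no_edges(self):
        em = seg.detect_edges(np.full((50, 50), 7.0))
        assert em.edges.sum() == 0

    def test_vertical_step_edge_at_step_column(self):
        img = np.zeros((40, 60))
        img[:, 30:] = 100.0
        em = seg.detect_edges(img)
        cols = np.argwhere(em.edges)[:, 1]
        assert cols.size > 0
        assert np.all(np.abs(cols - 29.5) <= 1.5)

    def test_edges_follow_true_boundary_of_render(self, noiseless_render):
        img, mask, _ = noiseless_render
        blurred = ndimage.gaussian_filter(img, 1.0)
        em = seg.detect_edges(blurred)
        boundary = mask & ~ndimage.binary_erosion(mask)
        dist_to_edge = ndimage.distance_transform_edt(~em.edges)
        frac = np.mean(dist_to_edge[boundary] <= 2.0)
        assert frac >= 0.95

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            seg.detect_edges(np.zeros((3, 3, 3)))


class TestCloseContours:
    @staticmethod
    def _ring(gap_px=0):
        img = np.zeros((60, 60), bool)
        rr, cc = circle_perimeter(30, 30, 18)
        img[rr, cc] = True
        if gap_px:
            img[28:28 + gap_px, 46:49] = False
        return img

    def test_closed_ring_unchanged(self):
        ring = self._ring()
        out = seg.close_contours(seg.EdgeMap(ring, ring.astype(float), 1.0))
        assert np.array_equal(out, ring)

    def test_small_gap_bridged(self):
        ring = self._ring(gap_px=3)
        out = seg.close_contours(seg.EdgeMap(ring, ring.astype(float), 1.0))
        added = out & ~ring
        assert added.sum() <= 4
        # bridged contour encloses a region again
        filled = ndimage.binary_fill_holes(out)
        assert filled.sum() > out.sum() + 100

    def test_gap_beyond_range_left_open(self):
        edges = np.zeros((40, 80), bool)
        edges[20, 5:20] = True
        edges[20, 31:46] = True  # 11-px gap > max_gap_px=10
        out = seg.close_contours(seg.EdgeMap(edges, edges.astype(float), 1.0), max_gap_px=10)
        assert np.array_equal(out, edges)


class TestMaskFromContours:
    def test_circle_contour_fills_to_disk(self):
        contour = np.zeros((60, 60), bool)
        rr, cc = circle_perimeter(30, 30, 10)
        contour[rr, cc] = True
        # without intensity information the filled mask carries the whole
        # 1-px contour ring (~+half-pixel of boundary)
        wm = seg.mask_from_contours(contour)
        assert not wm.failed
        assert wm.area == pytest.approx(np.pi * 100, rel=0.12)
        assert wm.qc_label == "unscored"
        # the half-max-refined mask reproduces the rasterized disk to 5%
        img = np.zeros((60, 60))
        rr, cc = disk((30, 30), 10.0)
        img[rr, cc] = 100.0
        wm2 = seg.mask_from_contours(contour, image=img, min_area_px=100)
        assert wm2.area == pytest.approx(np.pi * 100, rel=0.05)

    def test_nested_rings_hole_filled(self):
        contour = np.zeros((80, 80), bool)
        for r in (25, 12):
            rr, cc = circle_perimeter(40, 40, r)
            contour[rr, cc] = True
        wm = seg.mask_from_contours(contour)
        inner = np.zeros_like(contour)
        rr, cc = disk((40, 40), 10)
        inner[rr, cc] = True
        assert np.all(wm.mask[inner])

    def test_blank_contours_fail(self):
        wm = seg.mask_from_contours(np.zeros((50, 50), bool))
        assert wm.failed and wm.area == 0


class TestSegmentFrame:
    def test_oracle_equivalence_on_noiseless_render(self):
        js = []
        for s in range(5):
            rng = np.random.default_rng(s)
            img, mask, _ = syn.render_worm_frame(
                1.2e5, 100.0, (240, 240), 2.5, 20.0, 0.0, rng, blur_sigma=1.0
            )
            wm = seg.segment_frame(img.astype(float))
            js.append((wm.mask & mask).sum() / (wm.mask | mask).sum())
        assert min(js) >= 0.95

    def test_dimming_invariance(self):
        rng = np.random.default_rng(17)
        img, _, _ = syn.render_worm_frame(
            1.2e5, 100.0, (240, 240), 2.5, 20.0, 2.0, rng, blur_sigma=1.0
        )
        wm = seg.segment_frame(img.astype(float))
        wm_dim = seg.segment_frame(0.5 * img.astype(float))
        jac = (wm.mask & wm_dim.mask).sum() / (wm.mask | wm_dim.mask).sum()
        assert jac >= 0.98
        assert abs(wm_dim.area / wm.area - 1) < 0.01


class TestShapeFeatures:
    def test_constant_width_worm_low_width_cv(self):
        img, mask = syn.render_cylinder(5.0, 100)
        f = seg.features_from_mask(mask, img.astype(float))
        names = dict(zip(seg.FEATURE_NAMES, f.values))
        assert names["width_cv"] < 0.05

    def test_border_truncated_worm_contacts_border(self):
        mask = syn.truncated_worm_mask(1, 0.3)
        f = seg.features_from_mask(mask)
        names = dict(zip(seg.FEATURE_NAMES, f.values))
        assert names["border_contact_fraction"] > 0

    def test_deterministic(self, noiseless_render):
        img, mask, _ = noiseless_render
        a = seg.features_from_mask(mask, img)
        b = seg.features_from_mask(mask, img)
        assert np.array_equal(a.values, b.values)

    def test_failed_straightening_gives_sentinel(self):
        blob = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 15)
        blob[rr, cc] = True
        f = seg.features_from_mask(blob)
        assert f.is_sentinel


class TestQcClassifier:
    def test_default_ensemble_has_twenty_trees(self, trained_qc):
        assert trained_qc.n_trees == 20
        assert len(trained_qc.model.estimators_) == 20

    def test_separable_toy_features_high_oob(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(8, 1, (60, 3))])
        y = np.repeat([0, 1], 60)
        clf = seg.train_qc_classifier(x, y, seed=1)
        assert clf.oob_accuracy >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            seg.train_qc_classifier(np.zeros((10, 3)), np.zeros(10, dtype=int))

    def test_same_seed_identical_predictions(self, qc_features):
        (xtr, ytr, _), (xte, _, _) = qc_features
        a = seg.train_qc_classifier(xtr, ytr, seed=3)
        b = seg.train_qc_classifier(xtr, ytr, seed=3)
        pa = [seg.classify_frame(a, seg.ShapeFeatures(x)) for x in xte]
        pb = [seg.classify_frame(b, seg.ShapeFeatures(x)) for x in xte]
        assert pa == pb

    def test_sentinel_always_fails(self, trained_qc):
        label, score = seg.classify_frame(
            trained_qc, seg.ShapeFeatures(seg.SENTINEL_FEATURES.copy(), is_sentinel=True)
        )
        assert label == "fail" and score == 1.0

    def test_heldout_balanced_accuracy(self, trained_qc, qc_features):
        _, (xte, yte, _) = qc_features
        pred = np.array(
            [seg.classify_frame(trained_qc, seg.ShapeFeatures(x))[0] == "fail" for x in xte]
        )
        y = yte.astype(bool)
        balanced = 0.5 * (
            (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum()
        )
        assert balanced >= 0.9

    def test_score_monotone_in_truncation_severity(self, trained_qc):
        means = []
        for frac in (0.1, 0.2, 0.3, 0.4):
            scores = [
                seg.classify_frame(
                    trained_qc, seg.features_from_mask(syn.truncated_worm_mask(900 + s, frac))
                )[1]
                for s in range(10)
            ]
            means.append(np.mean(scores))
        assert np.all(np.diff(means) >= -1e-12)
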