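"""Hole filling, reclassification and volume refinement properties."""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from elbowrecon import metrics
from elbowrecon.mask_refine import fill_holes, reclassify, refine_volume


def border_flood_oracle(mask):
    """Fill oracle: 4-connected background flood fill from the border."""
    bg = ~np.asarray(mask, bool)
    padded = np.pad(bg, 1, constant_values=True)
    labels, _ = ndimage.label(padded)  # cross structure = 4-connectivity
    outside = labels == labels[0, 0]
    return ~outside[1:-1, 1:-1]


class TestFillHoles:
    def test_ring_hole_filled(self):
        ring = np.zeros((5, 5), bool)
        ring[1:4, 1:4] = True
        ring[2, 2] = False
        filled = fill_holes(ring)
        assert filled[2, 2]
        assert filled.sum() == 9

    def test_bay_open_to_border_not_filled(self):
        m = np.zeros((5, 5), bool)
        m[0:5, 0] = True
        m[0:5, 2] = True
        m[4, 1] = True  # U-shape: column 1 open at the top border
        filled = fill_holes(m)
        assert not filled[0, 1]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_border_flood_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12)) < 0.4
        filled = fill_holes(mask)
        assert np.array_equal(filled, border_flood_oracle(mask))
        assert (filled | mask).sum() == filled.sum()  # output superset of input

    def test_idempotent(self):
        rng = np.random.default_rng(21)
        mask = rng.random((20, 20)) < 0.45
        once = fill_holes(mask)
        assert np.array_equal(fill_holes(once), once)


class TestReclassify:
    def two_blob_scene(self):
        mask = np.zeros((16, 16), bool)
        mask[2:6, 2:6] = True
        mask[10:14, 10:14] = True
        recog = np.zeros((16, 16), bool)
        recog[3, 3] = True  # touches only the first blob
        return mask, recog

    def test_keeps_only_touching_component(self):
        mask, recog = self.two_blob_scene()
        out = reclassify(mask, recog)
        assert out[2:6, 2:6].all()
        assert not out[10:14, 10:14].any()

    def test_keeps_both_when_both_touch(self):
        mask, recog = self.two_blob_scene()
        recog[11, 11] = True
        out = reclassify(mask, recog)
        assert np.array_equal(out, mask)

    def test_empty_recognition_drops_mask(self):
        mask, _ = self.two_blob_scene()
        out = reclassify(mask, np.zeros_like(mask))
        assert not out.any()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_per_component_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((14, 14)) < 0.35
        recog = rng.random((14, 14)) < 0.1
        out = reclassify(mask, recog)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        expect = np.zeros_like(mask)
        for lab in range(1, n + 1):
            comp = labels == lab
            if (comp & recog).any():
                expect |= comp
        assert np.array_equal(out, expect)
        assert not (out & ~mask).any()  # output subset of input

    def test_idempotent(self):
        rng = np.random.default_rng(22)
        mask = rng.random((14, 14)) < 0.35
        recog = rng.random((14, 14)) < 0.15
        once = reclassify(mask, recog)
        assert np.array_equal(reclassify(once, recog), once)


class FakeRecognition:
    """Minimal stand-in exposing the RecognitionResult surface refine needs."""

    def __init__(self, masks_by_bone, spacing=(1.0, 1.0, 1.0)):
        self._masks = {k: np.asarray(v, bool) for k, v in masks_by_bone.items()}
        self._spacing = spacing

    def bone_mask(self, name, shape):
        return self._masks[name]

    def bone(self, name):
        from conftest import make_component

        idx = np.argwhere(self._masks[name])
        return make_component([tuple(i) for i in idx], self._spacing)


class TestRefineVolume:
    def overlap_scene(self):
        """Humerus prediction leaks into the ulna region on one slice."""
        shape = (3, 20, 20)
        hum_pred = np.zeros(shape, bool)
        uln_pred = np.zeros(shape, bool)
        hum_pred[1, 2:8, 2:18] = True  # includes a foreign blob at x 12:18
        hum_pred[1, 2:8, 8:12] = False  # split into two components
        uln_pred[1, 2:8, 12:18] = True
        hum_recog = np.zeros(shape, bool)
        hum_recog[1, 3:6, 3:6] = True
        uln_recog = np.zeros(shape, bool)
        uln_recog[1, 3:6, 13:16] = True
        recog = FakeRecognition({"humerus": hum_recog, "ulna": uln_recog})
        return {"humerus": hum_pred, "ulna": uln_pred}, recog

    def test_foreign_component_removed_and_iou_improves(self):
        preds, recog = self.overlap_scene()
        gt_hum = np.zeros((3, 20, 20), bool)
        gt_hum[1, 2:8, 2:8] = True
        before = metrics.iou(preds["humerus"][1], gt_hum[1])
        refined, report = refine_volume(preds, recog)
        after = metrics.iou(refined["humerus"][1], gt_hum[1])
        assert after > before
        assert not refined["humerus"][1, 2:8, 12:18].any()

    def test_disjoint_bones_only_hole_filling(self):
        shape = (2, 12, 12)
        pred = np.zeros(shape, bool)
        pred[0, 2:7, 2:7] = True
        pred[0, 4, 4] = False  # a hole
        recog = FakeRecognition({"humerus": pred.copy()})
        refined, _ = refine_volume({"humerus": pred}, recog)
        assert refined["humerus"][0, 4, 4]
        assert (refined["humerus"] | pred).sum() == refined["humerus"].sum()

    def test_processing_order_of_bones_is_irrelevant(self):
        preds, recog = self.overlap_scene()
        a, _ = refine_volume(dict(preds), recog)
        b, _ = refine_volume(dict(reversed(list(preds.items()))), recog)
        for bone in preds:
            assert np.array_equal(a[bone], b[bone])

    def test_overlap_voxels_assigned_to_nearer_bone(self):
        shape = (1, 10, 20)
        both = np.zeros(shape, bool)
        both[0, 2:8, 2:18] = True
        hum_recog = np.zeros(shape, bool)
        hum_recog[0, 4:6, 3:5] = True
        uln_recog = np.zeros(shape, bool)
        uln_recog[0, 4:6, 15:17] = True
        recog = FakeRecognition({"humerus": hum_recog, "ulna": uln_recog})
        refined, report = refine_volume(
            {"humerus": both.copy(), "ulna": both.copy()}, recog
        )
        assert report.overlap_voxels_before > 0
        assert not (refined["humerus"] & refined["ulna"]).any()
        assert refined["humerus"][0, 5, 3]  # near humerus seed
        assert refined["ulna"][0, 5, 16]  # near ulna seed
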