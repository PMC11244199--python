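"""Overlap metrics, surface error and order-statistic summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elbowrecon.errors import DataError
from elbowrecon.metrics import (
    dice,
    iou,
    per_slice_iou,
    summarize,
    surface_error,
)
from elbowrecon.reconstruction import SurfaceMesh, marching_cubes


class TestIoU:
    def test_identical_masks_give_one(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert iou(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert iou(a, b) == 0.0

    def test_nested_squares_quarter(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[0:4, 0:4] = True  # 16 px fully inside
        b[0:8, 0:8] = True  # 64 px
        assert iou(a, b) == pytest.approx(16 / 64)

    def test_both_empty_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0

    def test_shape_mismatch_errors(self):
        with pytest.raises(DataError):
            iou(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((10, 10)) < 0.5
        b = rng.random((10, 10)) < 0.5
        if not (a | b).any():
            a[0, 0] = True
        expect = (a & b).sum() / (a | b).sum()
        assert iou(a, b) == pytest.approx(expect)
        assert iou(a, b) == iou(b, a)
        assert 0.0 <= iou(a, b) <= 1.0

    def test_monotone_as_intersection_grows_with_union_fixed(self):
        union = np.zeros((10, 10), bool)
        union[2:8, 2:8] = True
        prev = -1.0
        for k in range(1, 7):
            a = np.zeros_like(union)
            a[2 : 2 + k, 2:8] = True
            value = iou(a, union)  # a inside union: union fixed, intersection grows
            assert value >= prev
            prev = value

    def test_dice_relates_to_iou(self):
        rng = np.random.default_rng(77)
        a = rng.random((12, 12)) < 0.5
        b = rng.random((12, 12)) < 0.5
        i = iou(a, b)
        assert dice(a, b) == pytest.approx(2 * i / (1 + i))


class TestPerSliceIoU:
    def test_perfect_prediction_all_ones(self):
        gt = np.zeros((4, 6, 6), bool)
        gt[1:3, 2:4, 2:4] = True
        curve = per_slice_iou(gt, gt)
        assert set(curve) == {1, 2}
        assert all(v == 1.0 for v in curve.values())

    def test_single_corrupted_slice_depressed(self):
        gt = np.zeros((4, 6, 6), bool)
        gt[1:4, 2:5, 2:5] = True
        pred = gt.copy()
        pred[2, 2, 2] = False
        curve = per_slice_iou(pred, gt)
        assert curve[1] == 1.0 and curve[3] == 1.0
        assert curve[2] < 1.0


class TestSurfaceError:
    def plate(self, offset=(0.0, 0.0, 0.0)):
        xs, ys = np.meshgrid(np.arange(20.0), np.arange(20.0))
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)]) + offset
        faces = []
        for j in range(19):
            for i in range(19):
                v = j * 20 + i
                faces.append([v, v + 1, v + 20])
                faces.append([v + 1, v + 21, v + 20])
        return SurfaceMesh(verts, np.array(faces))

    def test_identical_meshes_zero(self):
        m = self.plate()
        stats = surface_error(m, m)
        assert stats.max == pytest.approx(0.0, abs=1e-12)

    def test_unit_translation_of_plate(self):
        stats = surface_error(self.plate(), self.plate(offset=(0, 0, 1.0)))
        assert stats.max == pytest.approx(1.0, abs=1e-9)
        assert stats.mean == pytest.approx(1.0, abs=1e-9)

    def test_vertex_to_vertex_oracle_upper_bounds_vertex_to_triangle(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[3:11, 3:11, 3:11] = True
        cube = marching_cubes(mask)
        rng = np.random.default_rng(5)
        pred = SurfaceMesh(cube.vertices + rng.normal(0, 0.2, cube.vertices.shape), cube.faces)
        from scipy.spatial import cKDTree

        v2v = cKDTree(cube.vertices).query(pred.vertices, k=1)[0]
        stats = surface_error(pred, cube)
        assert stats.max <= v2v.max() + 1e-12
        assert stats.mean <= v2v.mean() + 1e-12

    def test_point_cloud_reference(self):
        m = self.plate()
        cloud = self.plate(offset=(0, 0, 0.5)).vertices
        stats = surface_error(m, cloud)
        assert stats.max == pytest.approx(0.5, abs=1e-9)

    def test_symmetric_variant_upper_bounds_forward(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        a = marching_cubes(mask)
        b = SurfaceMesh(a.vertices * 1.1, a.faces)
        fwd = surface_error(a, b)
        sym = surface_error(a, b, symmetric=True)
        assert sym.max >= fwd.max


class TestSummarize:
    def test_median_of_small_list(self):
        assert summarize([1, 2, 3, 4, 5])["median"] == 3.0

    def test_constant_list_zero_width_box(self):
        s = summarize([7.0] * 10)
        assert s["q1"] == s["q3"] == s["median"] == 7.0

    def test_matches_sorted_interpolation_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=37)
        s = summarize(values)
        srt = np.sort(values)

        def type7(p):
            h = (len(srt) - 1) * p
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert s["median"] == pytest.approx(type7(0.5))
        assert s["p10"] == pytest.approx(type7(0.10))
        assert s["q3"] == pytest.approx(type7(0.75))

    def test_empty_errors(self):
        with pytest.raises(DataError):
            summarize([])
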