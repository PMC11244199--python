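"""Recognition rules: thresholding, components, distance matrices, anatomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    brute_force_min_distance,
    component_from_points_mm,
    make_component,
    naive_flood_fill_labels,
)
from elbowrecon import phantom, recognition
from elbowrecon.ct_io import CTVolume
from elbowrecon.errors import AmbiguousSceneError, DataError, StageError
from elbowrecon.recognition import (
    RecognitionConfig,
    connected_components,
    forearm_axis,
    identify_ct_bed,
    identify_humerus,
    identify_ulna,
    min_distance_matrix,
    recognize,
    relative_distance_matrix,
    threshold_segment,
)


def volume_of(arr):
    return CTVolume(np.asarray(arr, np.float32), 1.0, 1.0)


class TestThreshold:
    def test_empty_foreground_advises_lower_threshold(self):
        vol = volume_of(np.zeros((3, 4, 4)))
        with pytest.raises(DataError, match="lower"):
            threshold_segment(vol, 200.0)

    def test_single_voxel_above_threshold(self):
        arr = np.zeros((3, 4, 4))
        arr[1, 2, 3] = 300.0
        mask = threshold_segment(volume_of(arr), 200.0)
        assert mask.sum() == 1 and mask[1, 2, 3]

    def test_cortical_shell_only_on_phantom(self):
        spec = phantom.PhantomSpec(noise_sigma=0.0, blur_sigma=0.0, seed=0)
        res = phantom.generate(spec)
        mask = threshold_segment(res.volume, 300.0)
        # direct count oracle: voxels >= 300 are exactly cortical (1100) + bed (300)
        assert mask.sum() == int((res.volume.voxels >= 300.0).sum())
        # no marrow voxel is included
        marrow = np.isclose(res.volume.voxels, spec.marrow_hu)
        assert not (mask & marrow).any()


class TestConnectedComponents:
    def test_two_disjoint_cubes(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[0:2, 0:2, 0:2] = True
        mask[4:6, 4:6, 4:6] = True
        comps = connected_components(mask)
        assert [c.size for c in comps] == [8, 8]

    def test_sorted_by_size_descending(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[5:7, 5:7, 5:7] = True  # 8 voxels
        mask[0:3, 0:3, 0:3] = True  # 27 voxels
        comps = connected_components(mask)
        assert [c.size for c in comps] == [27, 8]
        assert tuple(comps[0].voxel_indices[0]) == (0, 0, 0)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_naive_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(3)
        mask = rng.random((10, 10, 10)) < 0.3
        mask[0, 0, 0] = True
        comps = connected_components(mask, connectivity)
        got = {frozenset(map(tuple, c.voxel_indices)) for c in comps}
        assert got == naive_flood_fill_labels(mask, connectivity)

    def test_partitions_foreground(self):
        rng = np.random.default_rng(4)
        mask = rng.random((12, 12, 12)) < 0.2
        mask[3, 3, 3] = True
        comps = connected_components(mask)
        assert sum(c.size for c in comps) == int(mask.sum())

    def test_points_respect_anisotropy(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 2, 1] = True
        (c,) = connected_components(mask, spacing=(0.5, 0.5, 0.8))
        assert np.allclose(c.points_mm[0], [0.5, 1.0, 0.8])  # (x*ds, y*ds, z*dh)


class TestMinDistanceMatrix:
    def test_three_four_five(self):
        comps = [
            component_from_points_mm([[0, 0, 0]]),
            component_from_points_mm([[3, 4, 0]]),
            component_from_points_mm([[100, 0, 0]]),
            component_from_points_mm([[0, 100, 0]]),
        ]
        d = min_distance_matrix(comps)
        assert d[0, 1] == pytest.approx(5.0)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_shared_point_gives_zero(self):
        comps = [
            component_from_points_mm([[1, 1, 1], [5, 5, 5]]),
            component_from_points_mm([[1, 1, 1]]),
            component_from_points_mm([[9, 0, 0]]),
            component_from_points_mm([[0, 9, 0]]),
        ]
        assert min_distance_matrix(comps)[0, 1] == 0.0

    def test_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        clouds = [rng.normal(scale=10, size=(50, 3)) for _ in range(4)]
        comps = [component_from_points_mm(c) for c in clouds]
        d = min_distance_matrix(comps)
        for i in range(4):
            for j in range(i + 1, 4):
                assert d[i, j] == pytest.approx(
                    brute_force_min_distance(clouds[i], clouds[j]), abs=1e-9
                )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_zero_diagonal_property(self, seed):
        rng = np.random.default_rng(seed)
        comps = [component_from_points_mm(rng.normal(size=(8, 3))) for _ in range(4)]
        d = min_distance_matrix(comps)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0)


class TestBedAndHumerusRules:
    def test_bed_is_argmax_row_sum(self):
        d = np.array(
            [
                [0, 10, 9, 11],
                [10, 0, 3, 3],
                [9, 3, 0, 2],
                [11, 3, 2, 0],
            ],
            float,
        )
        assert identify_ct_bed(d) == 0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        d = rng.random((4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        d[2] += 10
        d[:, 2] += 10
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        base = identify_ct_bed(d)
        p = np.array([3, 0, 2, 1])  # d_perm[i, j] = d[p[i], p[j]]
        d_perm = d[np.ix_(p, p)]
        assert identify_ct_bed(d_perm) == int(np.where(p == base)[0][0])

    def test_tie_is_ambiguous(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(AmbiguousSceneError):
            identify_ct_bed(d)

    def test_humerus_row_sum_and_tie(self):
        assert identify_humerus(np.array([[0, 6, 6], [6, 0, 4], [6, 4, 0]], float)) == 0
        sym = np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0]], float)
        with pytest.raises(AmbiguousSceneError):
            identify_humerus(sym)


class TestRelativeDistance:
    def test_two_single_points(self):
        bones = [
            component_from_points_mm([[0, 0, 0]]),
            component_from_points_mm([[5, 0, 0]]),
            component_from_points_mm([[0, 12, 0]]),
        ]
        m = relative_distance_matrix(bones, n_samples=10)
        assert m[0, 1] == pytest.approx(5.0)
        assert np.all(np.diag(m) == 0)

    def test_matches_exhaustive_mean_of_min_oracle(self):
        rng = np.random.default_rng(7)
        clouds = [rng.normal(scale=5, size=(20, 3)) for _ in range(3)]
        bones = [component_from_points_mm(c) for c in clouds]
        m = relative_distance_matrix(bones, n_samples=100)  # all points sampled
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                d_ij = np.linalg.norm(
                    clouds[i][:, None, :] - clouds[j][None, :, :], axis=-1
                ).min(axis=1).mean()
                d_ji = np.linalg.norm(
                    clouds[j][:, None, :] - clouds[i][None, :, :], axis=-1
                ).min(axis=1).mean()
                assert m[i, j] == pytest.approx((d_ij + d_ji) / 2, abs=1e-9)


class TestForearmAxis:
    def test_hand_geometry_collinear_bones(self):
        humerus = make_component([(z, 0, 0) for z in range(10, 21)])
        forearm = [
            make_component([(z, 0, 0) for z in range(0, 5)]),
            make_component([(z, 0, 0) for z in range(5, 10)]),
        ]
        a, b, n_f = forearm_axis(humerus, forearm)
        assert np.allclose(a, [0, 0, 10])  # mm = (x, y, z)
        assert np.allclose(b, [0, 0, 0])
        assert np.allclose(n_f, [0, 0, 1.0])  # proximal = +z here

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(8)
        hum = rng.normal(size=(30, 3)) + [0, 0, 20]
        fore1 = rng.normal(size=(20, 3))
        fore2 = rng.normal(size=(20, 3)) + [0, 0, -10]
        a, b, n_f = forearm_axis(
            component_from_points_mm(hum),
            [component_from_points_mm(fore1), component_from_points_mm(fore2)],
        )
        from scipy.spatial.transform import Rotation

        r = Rotation.from_euler("xyz", [30, -40, 75], degrees=True).as_matrix()
        a2, b2, n2 = forearm_axis(
            component_from_points_mm(hum @ r.T),
            [component_from_points_mm(fore1 @ r.T), component_from_points_mm(fore2 @ r.T)],
        )
        assert np.allclose(a2, r @ a, atol=1e-9)
        assert np.allclose(n2, r @ n_f, atol=1e-9)

    def test_b_matches_exhaustive_farthest_point(self):
        rng = np.random.default_rng(9)
        hum = component_from_points_mm(rng.normal(size=(10, 3)) + [0, 0, 30])
        cloud = rng.normal(scale=4, size=(50, 3))
        fore = [component_from_points_mm(cloud[:25]), component_from_points_mm(cloud[25:])]
        a, b, _ = forearm_axis(hum, fore)
        expect = cloud[np.argmax(np.linalg.norm(cloud - a, axis=1))]
        assert np.allclose(b, expect)


class TestUlnaRule:
    def test_larger_projection_is_ulna(self):
        n_f = np.array([0.0, 0.0, 1.0])
        c1 = component_from_points_mm([[0, 0, z] for z in range(13)])  # extent 12
        c2 = component_from_points_mm([[2, 0, z] for z in range(10)])  # extent 9
        assert identify_ulna([c1, c2], n_f) == (0, 1)
        assert identify_ulna([c2, c1], n_f) == (1, 0)

    def test_tie_is_ambiguous(self):
        n_f = np.array([0.0, 0.0, 1.0])
        c1 = component_from_points_mm([[0, 0, 5]])
        c2 = component_from_points_mm([[3, 3, 5]])
        with pytest.raises(AmbiguousSceneError):
            identify_ulna([c1, c2], n_f)


class TestRecognize:
    def test_phantom_labels_all_correct(self, default_phantom):
        result = recognize(default_phantom.volume)
        for bone, value in (("humerus", 1), ("ulna", 2), ("radius", 3)):
            idx = result.components[bone].voxel_indices
            gt = default_phantom.labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
            assert (gt == value).all(), f"{bone} voxels mislabeled"
        bed_idx = result.components["ct_bed"].voxel_indices
        assert (default_phantom.labels.labels[bed_idx[:, 0], bed_idx[:, 1], bed_idx[:, 2]] == 0).all()

    @pytest.mark.parametrize("flexion", [82.0, 170.0])
    def test_extreme_flexion_angles(self, flexion):
        res = phantom.generate(phantom.PhantomSpec(flexion_angle=flexion, seed=11))
        result = recognize(res.volume)
        for bone, value in (("humerus", 1), ("ulna", 2), ("radius", 3)):
            idx = result.components[bone].voxel_indices
            gt = res.labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
            assert (gt == value).all()

    def test_too_few_components_names_stage(self):
        arr = np.zeros((4, 8, 8), np.float32)
        arr[1, 2, 2] = 500.0
        arr[2, 5, 5] = 500.0
        vol = CTVolume(arr, 1.0, 1.0)
        with pytest.raises(StageError, match="components"):
            recognize(vol, RecognitionConfig(auto_retry=False))

    def test_result_export_roundtrip(self, tmp_path, default_phantom):
        result = recognize(default_phantom.volume)
        result.save_json(tmp_path / "r.json")
        import json

        loaded = json.loads((tmp_path / "r.json").read_text())
        assert set(loaded["components"]) == {"ct_bed", "humerus", "ulna", "radius"}
        assert abs(np.linalg.norm(loaded["forearm_axis"]) - 1) < 1e-9
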