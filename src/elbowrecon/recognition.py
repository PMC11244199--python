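"""Anatomical recognition of the CT bed, humerus, ulna and radius.

The scene model: a thresholded unilateral elbow CT contains four dominant
connected components — the three bones and the scanner bed.  Identification
uses only inter-component geometry:

1. **CT bed** — the joint spaces are narrow while the bed lies far from every
   bone, so the bed is the component whose row of the 4x4 minimum-distance
   matrix has the largest sum.
2. **Humerus** — among the three bones, the ulna and radius run parallel and
   close together, so the humerus is the component with the largest row sum
   of the 3x3 *relative* (mean nearest-point) distance matrix.
3. **Ulna vs radius** — the forearm axis is estimated from A (the distal
   point of the humerus) and B (the forearm point farthest from A); the
   olecranon makes the ulna reach farther proximally along this axis than
   the radial head, so the component with the larger maximum projection is
   the ulna.

All distances are in millimetres (anisotropy-aware voxel centers).  Argmax
ties within 1e-9 raise :class:`AmbiguousSceneError` — the anatomical
assumption backing the rule is then violated and a silent choice would be
wrong more often than not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .ct_io import CTVolume
from .errors import AmbiguousSceneError, AnatomicalAssumptionError, DataError, StageError

_TIE_TOL = 1e-9

ANATOMICAL_LABELS = ("ct_bed", "humerus", "ulna", "radius")
#: label values used when exporting a bone label volume
BONE_LABEL_VALUES = {"humerus": 1, "ulna": 2, "radius": 3}


@dataclass
class ConnectedComponent:
    """A labeled set of foreground voxels.

    ``voxel_indices`` is an (N, 3) int array of (z, y, x) indices in raster
    order; ``points_mm`` is the matching (N, 3) float array of voxel centers
    (x*spacing, y*spacing, z*slice_distance) in mm.
    """

    id: int
    voxel_indices: np.ndarray
    points_mm: np.ndarray

    @property
    def size(self) -> int:
        return len(self.voxel_indices)

    def slice_range(self) -> tuple[int, int]:
        z = self.voxel_indices[:, 0]
        return int(z.min()), int(z.max())

    def bounding_box(self) -> dict[str, int]:
        z, y, x = (self.voxel_indices[:, i] for i in range(3))
        return {
            "z_min": int(z.min()), "z_max": int(z.max()),
            "y_min": int(y.min()), "y_max": int(y.max()),
            "x_min": int(x.min()), "x_max": int(x.max()),
        }


@dataclass
class DistanceMatrices:
    """Minimum (4x4) and relative mean (3x3) inter-component distances, mm."""

    d_min: np.ndarray
    d_mean: np.ndarray


@dataclass
class RecognitionResult:
    """Anatomical assignment plus the geometry that justified it."""

    components: dict[str, ConnectedComponent]
    matrices: DistanceMatrices
    point_a: np.ndarray
    point_b: np.ndarray
    forearm_axis: np.ndarray
    threshold_used: float = float("nan")

    def bone(self, name: str) -> ConnectedComponent:
        return self.components[name]

    def bone_mask(self, name: str, shape: tuple[int, int, int]) -> np.ndarray:
        """Binary volume of the recognized voxels of one bone."""
        out = np.zeros(shape, dtype=bool)
        idx = self.components[name].voxel_indices
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return out

    def label_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Int16 volume with humerus=1, ulna=2, radius=3 (recognized voxels)."""
        out = np.zeros(shape, dtype=np.int16)
        for name, value in BONE_LABEL_VALUES.items():
            idx = self.components[name].voxel_indices
            out[idx[:, 0], idx[:, 1], idx[:, 2]] = value
        return out

    def to_json_dict(self) -> dict:
        return {
            "threshold_used": self.threshold_used,
            "point_a_mm": self.point_a.tolist(),
            "point_b_mm": self.point_b.tolist(),
            "forearm_axis": self.forearm_axis.tolist(),
            "d_min_mm": self.matrices.d_min.tolist(),
            "d_mean_mm": self.matrices.d_mean.tolist(),
            "components": {
                name: {"voxel_count": comp.size, "bounding_box": comp.bounding_box()}
                for name, comp in self.components.items()
            },
        }

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))


@dataclass
class RecognitionConfig:
    """Tunable parameters of the recognition stage.

    threshold : initial segmentation threshold in HU.  It must be low enough
        to capture cortical bone everywhere but high enough that blurred
        joint spaces do not fuse adjacent bones.
    connectivity : 26 (default) or 6 neighborhood for component labeling.
    n_samples : points sampled per component for relative distances.
    auto_retry : if fewer than 4 components are found (bone adhesion
        suspected), retry with the threshold raised in +50 HU steps.
    """

    threshold: float = 250.0
    connectivity: int = 26
    n_samples: int = 100
    auto_retry: bool = True
    retry_step: float = 50.0
    retry_max: float = 500.0


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


def threshold_segment(volume: CTVolume, threshold: float) -> np.ndarray:
    """Binary mask of voxels with intensity >= ``threshold`` (HU)."""
    if not np.isfinite(threshold):
        raise DataError("threshold must be finite")
    mask = volume.voxels >= threshold
    if not mask.any():
        raise DataError(
            f"threshold {threshold} HU leaves an empty foreground; lower the threshold"
        )
    return mask


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise DataError(f"connectivity must be 6 or 26, got {connectivity}")


def connected_components(
    mask: np.ndarray,
    connectivity: int = 26,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[ConnectedComponent]:
    """Label ``mask`` and return components sorted by size (descending).

    Ties are broken by the smallest (z, y, x) raster index of the component.
    ``spacing`` is (pixel, pixel, slice) mm used to populate ``points_mm``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DataError("mask is empty; nothing to label")
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n + 1)
    # first occurrence in raster order == smallest (z, y, x) index
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed scatter leaves the *first* occurrence in place
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = sorted(range(1, n + 1), key=lambda l: (-counts[l], first_idx[l]))

    ds, dh = float(spacing[0]), float(spacing[2])
    comps = []
    objects = ndimage.find_objects(labels)
    for new_id, lab in enumerate(order):
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        zz, yy, xx = np.nonzero(sub)
        idx = np.column_stack([zz + sl[0].start, yy + sl[1].start, xx + sl[2].start])
        pts = np.column_stack([idx[:, 2] * ds, idx[:, 1] * ds, idx[:, 0] * dh])
        comps.append(ConnectedComponent(new_id, idx.astype(np.int64), pts.astype(float)))
    return comps


def min_distance_matrix(components: list[ConnectedComponent]) -> np.ndarray:
    """Pairwise minimum Euclidean distance (mm) between components (KD-tree)."""
    n = len(components)
    if n != 4:
        raise DataError(f"expected exactly 4 components, got {n}")
    trees = [cKDTree(c.points_mm) for c in components]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # query the smaller cloud against the larger tree
            if components[i].size <= components[j].size:
                dist, _ = trees[j].query(components[i].points_mm, k=1)
            else:
                dist, _ = trees[i].query(components[j].points_mm, k=1)
            d[i, j] = d[j, i] = float(dist.min())
    return d


def identify_ct_bed(d_min: np.ndarray) -> int:
    """Index of the bed: argmax of row sums of the minimum-distance matrix."""
    d_min = np.asarray(d_min, dtype=float)
    if d_min.shape != (4, 4) or not np.allclose(d_min, d_min.T):
        raise DataError("d_min must be a symmetric 4x4 matrix")
    sums = d_min.sum(axis=1)
    order = np.argsort(sums)[::-1]
    if sums[order[0]] - sums[order[1]] < _TIE_TOL:
        raise AmbiguousSceneError(
            "CT-bed rule is ambiguous: two components are equally distant from the rest "
            "(the bed is assumed farther from the bones than any joint gap)"
        )
    return int(order[0])


def _stride_sample(points: np.ndarray, n_samples: int) -> np.ndarray:
    """Deterministic uniform stride over the raster-ordered point list."""
    if n_samples >= len(points):
        return points
    idx = np.linspace(0, len(points) - 1, n_samples).round().astype(int)
    return points[idx]


def relative_distance_matrix(
    bones: list[ConnectedComponent], n_samples: int = 100
) -> np.ndarray:
    """Symmetrized mean nearest-point distance (mm) among three components.

    For entry (i, j): ``n_samples`` points are chosen from component i by
    uniform stride over its raster-ordered voxel list, the distance of each
    to the nearest point of component j is taken, and the mean is recorded;
    the matrix is then symmetrized as (M + M.T) / 2.
    """
    if len(bones) != 3:
        raise DataError(f"expected exactly 3 components, got {len(bones)}")
    if n_samples < 1:
        raise DataError("n_samples must be >= 1")
    trees = [cKDTree(b.points_mm) for b in bones]
    samples = [_stride_sample(b.points_mm, n_samples) for b in bones]
    m = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            dist, _ = trees[j].query(samples[i], k=1)
            m[i, j] = float(dist.mean())
    return (m + m.T) / 2.0


def identify_humerus(d_mean: np.ndarray) -> int:
    """Index of the humerus: argmax of row sums of the relative-distance matrix."""
    d_mean = np.asarray(d_mean, dtype=float)
    if d_mean.shape != (3, 3):
        raise DataError("d_mean must be a 3x3 matrix")
    sums = d_mean.sum(axis=1)
    order = np.argsort(sums)[::-1]
    if sums[order[0]] - sums[order[1]] < _TIE_TOL:
        raise AmbiguousSceneError(
            "humerus rule is ambiguous: no component is clearly farther from the "
            "close ulna-radius pair"
        )
    return int(order[0])


def forearm_axis(
    humerus: ConnectedComponent, forearm_components: list[ConnectedComponent]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate the forearm shaft axis.

    Returns (A, B, n_f): A is the humerus point nearest the union of the two
    forearm components (the joint-facing, distal end of the humerus); B is
    the forearm point farthest from A; n_f = (A - B)/||A - B|| points
    *proximally* (from the hand toward the shoulder), so that the olecranon
    gives the ulna the larger projection.
    """
    forearm_points = np.vstack([c.points_mm for c in forearm_components])
    tree = cKDTree(forearm_points)
    dist, _ = tree.query(humerus.points_mm, k=1)
    a = humerus.points_mm[int(np.argmin(dist))]
    d2 = np.einsum("ij,ij->i", forearm_points - a, forearm_points - a)
    b = forearm_points[int(np.argmax(d2))]
    ab = a - b
    norm = np.linalg.norm(ab)
    if norm == 0:
        raise AnatomicalAssumptionError("degenerate forearm axis: A equals B")
    return a, b, ab / norm


def identify_ulna(
    forearm_components: list[ConnectedComponent], n_f: np.ndarray
) -> tuple[int, int]:
    """Disambiguate ulna and radius by maximum projection onto the forearm axis.

    The component reaching farther proximally (the olecranon) is the ulna.
    Returns (ulna index, radius index) into ``forearm_components``.
    """
    if len(forearm_components) != 2:
        raise DataError("exactly two forearm components are required")
    n_f = np.asarray(n_f, dtype=float)
    if abs(np.linalg.norm(n_f) - 1.0) > 1e-9:
        raise DataError("forearm axis must be a unit vector")
    pp = [float(np.max(c.points_mm @ n_f)) for c in forearm_components]
    if abs(pp[0] - pp[1]) < _TIE_TOL:
        raise AmbiguousSceneError(
            "ulna/radius rule is ambiguous: equal proximal extents along the forearm axis"
        )
    ulna = int(np.argmax(pp))
    return ulna, 1 - ulna


# ---------------------------------------------------------------------------
# Composite
# ---------------------------------------------------------------------------


def recognize(volume: CTVolume, config: RecognitionConfig | None = None) -> RecognitionResult:
    """Full recognition: threshold, label, and assign the four anatomical roles."""
    config = config or RecognitionConfig()
    spacing = (volume.pixel_spacing, volume.pixel_spacing, volume.slice_distance)

    threshold = config.threshold
    while True:
        try:
            mask = threshold_segment(volume, threshold)
            comps = connected_components(mask, config.connectivity, spacing)
        except DataError as exc:
            raise StageError("threshold", str(exc)) from exc
        if len(comps) >= 4:
            break
        if config.auto_retry and threshold + config.retry_step <= config.retry_max:
            threshold += config.retry_step  # adhesion suspected: split by raising
            continue
        raise StageError(
            "components",
            f"found only {len(comps)} connected component(s) at {threshold} HU; "
            "a standard elbow scene needs 4 (bed, humerus, ulna, radius)",
        )

    top4 = comps[:4]
    d_min = min_distance_matrix(top4)
    try:
        bed_idx = identify_ct_bed(d_min)
    except AmbiguousSceneError as exc:
        raise StageError("ct_bed", str(exc)) from exc

    bones = [c for i, c in enumerate(top4) if i != bed_idx]
    d_mean = relative_distance_matrix(bones, config.n_samples)
    try:
        hum_idx = identify_humerus(d_mean)
    except AmbiguousSceneError as exc:
        raise StageError("humerus", str(exc)) from exc

    humerus = bones[hum_idx]
    forearm = [c for i, c in enumerate(bones) if i != hum_idx]
    a, b, n_f = forearm_axis(humerus, forearm)
    try:
        ulna_idx, radius_idx = identify_ulna(forearm, n_f)
    except AmbiguousSceneError as exc:
        raise StageError("ulna_radius", str(exc)) from exc

    return RecognitionResult(
        components={
            "ct_bed": top4[bed_idx],
            "humerus": humerus,
            "ulna": forearm[ulna_idx],
            "radius": forearm[radius_idx],
        },
        matrices=DistanceMatrices(d_min=d_min, d_mean=d_mean),
        point_a=a,
        point_b=b,
        forearm_axis=n_f,
        threshold_used=threshold,
    )
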