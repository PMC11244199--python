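"""Synthetic elbow CT phantoms with exact ground truth.

Clinical elbow CT with expert labels is not shareable, so every stage of the
pipeline is exercised on phantoms that embody the anatomical structure the
recognition rules rely on:

* three elongated bones built from analytic primitives (capsules and
  spheres) — a humerus with a flared distal end (trochlea sphere), an ulna
  whose proximal hook (olecranon, a capsule-chain arc) wraps the trochlea at
  exactly ``joint_gap`` separation, and a radius whose spherical head starts
  distal of the olecranon tip by ``olecranon_overhang`` along the forearm
  axis;
* a forearm rotated about the elbow by a configurable flexion angle
  (validated range 82°–170°);
* a scanner-bed slab placed ``bed_offset`` mm from the nearest bone — much
  farther than any joint gap, as the bed-identification rule assumes;
* a ~2 mm high-intensity cortical shell around a low-intensity marrow
  cavity, Gaussian blur (partial-volume emulation) and Gaussian noise.

Ground-truth labels are the *solid* bone interiors (shell + marrow).
Analytic surface point clouds are retained so reconstructed meshes can be
scored against exact geometry.

The humeral distal neck is tilted out of the flexion plane; a humerus that
stays convex inside the flexion plane would intersect the wrapped olecranon
at some flexion angle (real anatomy avoids this with the concave olecranon
fossa, which convex primitives cannot express).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .ct_io import CTVolume, LabelMask
from .errors import AnatomicalAssumptionError

BONE_NAMES = {1: "humerus", 2: "ulna", 3: "radius"}

# Fixed scene layout (mm); the flexion angle, gaps and overhang are the
# anatomy-bearing knobs exposed on PhantomSpec.
_FOV_X = 96.0
_FOV_Z = 120.0
_TROCHLEA = np.array([30.0, 30.0, 64.0])  # trochlea center (x, y, z) mm
_R_TROCHLEA = 9.0
_R_NECK = 3.5
_NECK_LEN = 20.0
_NECK_TILT_DEG = 50.0  # out-of-plane (toward +y) tilt of the distal humerus
_HUM_SHAFT_LEN = 30.0
_R_HUM_SHAFT = 7.0
_R_ULNA = 5.0
_ULNA_LEN = 40.0
_R_OLECRANON = 5.0
_R_RAD_HEAD = 5.0
_R_RAD_SHAFT = 4.5
_RAD_LEN = 34.0
_RAD_Y_OFFSET = 12.0
_BED_THICKNESS = 5.0
_ARC_SEGMENTS = 10
_SURFACE_SAMPLE_MM = 0.35


@dataclass
class PhantomSpec:
    """Parameters of one synthetic elbow scene.

    flexion_angle : angle between humeral shaft and forearm axis, degrees;
        valid range 82–170 (flexion to extension).
    pixel_spacing / slice_distance : voxel geometry, mm (clinical ranges
        0.29–0.57 and 0.8 respectively).
    joint_gap : humeroulnar minimum separation, mm; must stay well below
        ``bed_offset`` or the bed rule's assumption fails.
    bed_offset : distance from the nearest bone to the bed slab, mm.
    olecranon_overhang : how much farther the olecranon reaches proximally
        than any radius point, along the forearm axis, mm.
    shell_thickness : cortical shell thickness, mm.
    blur_sigma : Gaussian blur in voxels (partial-volume emulation).
    noise_sigma : additive Gaussian noise, HU.
    shape : optional (nz, ny, nx) override; derived from the fixed
        field of view when None.
    """

    flexion_angle: float = 110.0
    pixel_spacing: float = 0.43
    slice_distance: float = 0.8
    shape: tuple[int, int, int] | None = None
    cortical_hu: float = 1100.0
    marrow_hu: float = 150.0
    soft_tissue_hu: float = 40.0
    bed_hu: float = 300.0
    joint_gap: float = 2.5
    bed_offset: float = 25.0
    olecranon_overhang: float = 8.0
    shell_thickness: float = 2.0
    noise_sigma: float = 15.0
    blur_sigma: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if not 82.0 <= self.flexion_angle <= 170.0:
            raise AnatomicalAssumptionError(
                f"flexion angle {self.flexion_angle}° outside the validated 82°–170° range"
            )
        if not self.joint_gap < self.bed_offset:
            raise AnatomicalAssumptionError(
                "joint_gap must be smaller than bed_offset: the bed rule assumes the "
                "joint space is narrower than the bone-to-bed distance"
            )
        if self.olecranon_overhang <= 0:
            raise AnatomicalAssumptionError(
                "olecranon_overhang must be positive: the ulna/radius rule assumes the "
                "olecranon reaches farther proximally than the radial head"
            )
        if self.joint_gap < 1.0:
            raise AnatomicalAssumptionError(
                "joint_gap below 1 mm risks bone adhesion at the initial threshold"
            )
        if not (self.pixel_spacing > 0 and self.slice_distance > 0):
            raise AnatomicalAssumptionError("voxel spacings must be positive")
        cos_end = self._arc_end_cos()
        if not -0.55 < cos_end < 0.95:
            raise AnatomicalAssumptionError(
                f"olecranon_overhang {self.olecranon_overhang} mm cannot be realized by "
                "the olecranon arc for this joint geometry"
            )

    # -- derived geometry -------------------------------------------------

    @property
    def _arc_radius(self) -> float:
        return _R_TROCHLEA + self.joint_gap + _R_OLECRANON

    @property
    def _rad_head_axial(self) -> float:
        """Distal offset (along forearm axis) of the radial head center."""
        reach = _R_TROCHLEA + _R_RAD_HEAD + self.joint_gap + 1.0
        return math.sqrt(reach**2 - _RAD_Y_OFFSET**2)

    def _arc_end_cos(self) -> float:
        # olecranon tip proximal extent = -R_arc*cos(psi_end) + r_olecranon;
        # radial head proximal extent = -rad_head_axial + r_head; their
        # difference is the requested overhang.
        return (
            _R_OLECRANON + self._rad_head_axial - _R_RAD_HEAD - self.olecranon_overhang
        ) / self._arc_radius


@dataclass
class PhantomResult:
    """A generated phantom: CT volume, ground-truth labels, analytic surfaces."""

    volume: CTVolume
    labels: LabelMask
    surfaces: dict[str, np.ndarray]
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Analytic primitives
# ---------------------------------------------------------------------------


class _Sphere:
    def __init__(self, center, r):
        self.center = np.asarray(center, float)
        self.r = float(r)

    def bbox(self):
        return self.center - self.r, self.center + self.r

    def sdf(self, pts):
        return np.linalg.norm(pts - self.center, axis=-1) - self.r

    def sample(self, spacing):
        n = max(32, int(4 * math.pi * self.r**2 / spacing**2))
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = math.pi * (1 + 5**0.5) * i
        d = np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
        return self.center + self.r * d


class _Capsule:
    def __init__(self, a, b, r):
        self.a = np.asarray(a, float)
        self.b = np.asarray(b, float)
        self.r = float(r)

    def bbox(self):
        lo = np.minimum(self.a, self.b) - self.r
        hi = np.maximum(self.a, self.b) + self.r
        return lo, hi

    def sdf(self, pts):
        ab = self.b - self.a
        denom = float(ab @ ab)
        pa = pts - self.a
        h = np.clip(pa @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(pts.shape[:-1])
        return np.linalg.norm(pa - h[..., None] * ab, axis=-1) - self.r

    def sample(self, spacing):
        ab = self.b - self.a
        length = np.linalg.norm(ab)
        pieces = [_Sphere(self.a, self.r).sample(spacing), _Sphere(self.b, self.r).sample(spacing)]
        if length > 0:
            axis = ab / length
            # orthonormal frame around the axis
            ref = np.array([1.0, 0.0, 0.0])
            if abs(axis @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            u = np.cross(axis, ref)
            u /= np.linalg.norm(u)
            v = np.cross(axis, u)
            n_t = max(2, int(length / spacing))
            n_c = max(8, int(2 * math.pi * self.r / spacing))
            t = np.linspace(0, 1, n_t)
            ang = np.linspace(0, 2 * math.pi, n_c, endpoint=False)
            circ = self.r * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
            pts = (self.a + np.outer(t, ab))[:, None, :] + circ[None, :, :]
            pieces.append(pts.reshape(-1, 3))
        return np.vstack(pieces)


def _union_sdf_at(primitives, pts):
    d = np.full(pts.shape[:-1], np.inf)
    for p in primitives:
        np.minimum(d, p.sdf(pts), out=d)
    return d


def _surface_points(primitives, spacing=_SURFACE_SAMPLE_MM):
    """Sample the boundary of a union of primitives: per-primitive surface
    samples, discarding points strictly inside any other primitive."""
    keep = []
    for i, p in enumerate(primitives):
        pts = p.sample(spacing)
        inside = np.zeros(len(pts), dtype=bool)
        for j, q in enumerate(primitives):
            if j != i:
                inside |= q.sdf(pts) < -1e-9
        keep.append(pts[~inside])
    return np.vstack(keep)


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------


def _scene_primitives(spec: PhantomSpec) -> dict[str, list]:
    """Analytic primitives per bone, in scene millimetres."""
    t = _TROCHLEA
    phi = math.radians(180.0 - spec.flexion_angle)
    d_f = np.array([math.sin(phi), 0.0, -math.cos(phi)])  # distal forearm direction
    p_f = np.array([math.cos(phi), 0.0, math.sin(phi)])  # in-plane perpendicular

    tilt = math.radians(_NECK_TILT_DEG)
    u_neck = np.array([0.0, math.sin(tilt), math.cos(tilt)])
    neck_end = t + _NECK_LEN * u_neck
    humerus = [
        _Sphere(t, _R_TROCHLEA),
        _Capsule(t, neck_end, _R_NECK),
        _Capsule(neck_end, neck_end + np.array([0.0, 0.0, _HUM_SHAFT_LEN]), _R_HUM_SHAFT),
    ]

    r_arc = spec._arc_radius
    c1 = t + (_R_TROCHLEA + spec.joint_gap + _R_ULNA) * d_f
    ulna = [_Capsule(c1, c1 + _ULNA_LEN * d_f, _R_ULNA)]
    psi_end = math.acos(spec._arc_end_cos())
    psis = np.linspace(0.0, psi_end, _ARC_SEGMENTS + 1)
    arc = [t + r_arc * (math.cos(ps) * d_f + math.sin(ps) * p_f) for ps in psis]
    ulna += [_Capsule(arc[k], arc[k + 1], _R_OLECRANON) for k in range(_ARC_SEGMENTS)]

    head = t + spec._rad_head_axial * d_f + np.array([0.0, _RAD_Y_OFFSET, 0.0])
    radius = [
        _Sphere(head, _R_RAD_HEAD),
        _Capsule(head, head + _RAD_LEN * d_f, _R_RAD_SHAFT),
    ]
    return {"humerus": humerus, "ulna": ulna, "radius": radius}


def _bed_geometry(spec: PhantomSpec) -> tuple[float, float]:
    """(y_start, y_stop) of the bed slab in mm."""
    bones_max_y = _TROCHLEA[1] + _NECK_LEN * math.sin(math.radians(_NECK_TILT_DEG)) + _R_HUM_SHAFT
    y0 = bones_max_y + spec.bed_offset
    return y0, y0 + _BED_THICKNESS


def _fov(spec: PhantomSpec) -> tuple[float, float, float]:
    _, bed_y1 = _bed_geometry(spec)
    return _FOV_X, bed_y1 + 3.0, _FOV_Z


def _check_scene(spec: PhantomSpec, prims: dict[str, list]) -> None:
    """Numerically verify the distance orderings the recognition rules need."""
    clouds = {b: _surface_points(p, spacing=0.8) for b, p in prims.items()}
    trees = {b: cKDTree(c) for b, c in clouds.items()}
    gaps = {}
    for a, b in (("humerus", "ulna"), ("humerus", "radius"), ("ulna", "radius")):
        d, _ = trees[b].query(clouds[a], k=1)
        gaps[(a, b)] = float(d.min())
    if min(gaps.values()) < 1.0:
        pair = min(gaps, key=gaps.get)  # type: ignore[arg-type]
        raise AnatomicalAssumptionError(
            f"bones {pair} come within {gaps[pair]:.2f} mm; the scene risks adhesion "
            "at the initial threshold"
        )
    if max(gaps.values()) >= spec.bed_offset:
        raise AnatomicalAssumptionError(
            "an inter-bone gap is not smaller than the bed offset; the bed rule's "
            "assumption is violated"
        )


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def _voxelize_bone(primitives, shape, ds, dh) -> np.ndarray:
    """Signed distance (mm) of a primitive union on the (z, y, x) grid,
    evaluated only inside each primitive's bounding box."""
    nz, ny, nx = shape
    sdf = np.full(shape, np.inf, dtype=np.float32)
    for p in primitives:
        lo, hi = p.bbox()
        margin = 1.0
        x0, x1 = int(max(0, (lo[0] - margin) / ds)), int(min(nx - 1, (hi[0] + margin) / ds)) + 1
        y0, y1 = int(max(0, (lo[1] - margin) / ds)), int(min(ny - 1, (hi[1] + margin) / ds)) + 1
        z0, z1 = int(max(0, (lo[2] - margin) / dh)), int(min(nz - 1, (hi[2] + margin) / dh)) + 1
        xs = (np.arange(x0, x1) * ds)[None, None, :, None]
        ys = (np.arange(y0, y1) * ds)[None, :, None, None]
        zs = (np.arange(z0, z1) * dh)[:, None, None, None]
        pts = np.concatenate(np.broadcast_arrays(xs, ys, zs), axis=-1)
        np.minimum(
            sdf[z0:z1, y0:y1, x0:x1], p.sdf(pts).astype(np.float32), out=sdf[z0:z1, y0:y1, x0:x1]
        )
    return sdf


def generate(spec: PhantomSpec) -> PhantomResult:
    """Generate one phantom (CT volume, GT labels, analytic surface clouds)."""
    spec.validate()
    prims = _scene_primitives(spec)
    _check_scene(spec, prims)

    ds, dh = spec.pixel_spacing, spec.slice_distance
    if spec.shape is not None:
        shape = tuple(spec.shape)
    else:
        fx, fy, fz = _fov(spec)
        shape = (int(round(fz / dh)), int(round(fy / ds)), int(round(fx / ds)))
    nz, ny, nx = shape

    hu = np.full(shape, spec.soft_tissue_hu, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int16)

    bed_y0, bed_y1 = _bed_geometry(spec)
    j0, j1 = int(np.ceil(bed_y0 / ds)), int(np.floor(bed_y1 / ds)) + 1
    x0, x1 = int(np.ceil(8.0 / ds)), int(np.floor((_FOV_X - 8.0) / ds)) + 1
    z0, z1 = int(np.ceil(8.0 / dh)), int(np.floor((_FOV_Z - 8.0) / dh)) + 1
    hu[z0:z1, j0 : min(j1, ny), x0:x1] = spec.bed_hu

    surfaces = {}
    for value, bone in BONE_NAMES.items():
        sdf = _voxelize_bone(prims[bone], shape, ds, dh)
        solid = sdf <= 0.0
        labels[solid] = value
        hu[solid & (sdf < -spec.shell_thickness)] = spec.marrow_hu
        hu[solid & (sdf >= -spec.shell_thickness)] = spec.cortical_hu
        surfaces[bone] = _surface_points(prims[bone])

    if spec.blur_sigma > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.blur_sigma)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)

    volume = CTVolume(hu.astype(np.float32), ds, dh)
    mask = LabelMask(labels, dict(BONE_NAMES))
    return PhantomResult(volume, mask, surfaces, spec)


# ---------------------------------------------------------------------------
# Suites
# ---------------------------------------------------------------------------


def suite_specs(
    n: int,
    seed: int,
    flexion_range: tuple[float, float] = (82.0, 170.0),
    spacing_range: tuple[float, float] = (0.29, 0.57),
) -> list[PhantomSpec]:
    """``n`` reproducible specs with flexion and spacing sampled over the
    clinical ranges and distinct sub-seeds."""
    if n < 1:
        raise AnatomicalAssumptionError("suite size must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        specs.append(
            PhantomSpec(
                flexion_angle=float(rng.uniform(*flexion_range)),
                pixel_spacing=float(rng.uniform(*spacing_range)),
                seed=int(rng.integers(2**31)),
            )
        )
    return specs


def generate_suite(n: int, seed: int) -> list[PhantomResult]:
    """Generate ``n`` phantoms sampled over the clinical flexion/spacing ranges."""
    return [generate(s) for s in suite_specs(n, seed)]


def flexion_grid_specs(
    seed: int,
    flexions: tuple[float, ...] = (82.0, 100.0, 120.0, 140.0, 170.0),
    seeds_per_angle: int = 5,
    spacing_range: tuple[float, float] = (0.29, 0.57),
) -> list[PhantomSpec]:
    """Flexion-grid validation suite: each listed angle x ``seeds_per_angle``
    random (spacing, noise seed) draws."""
    rng = np.random.default_rng(seed)
    specs = []
    for angle in flexions:
        for _ in range(seeds_per_angle):
            specs.append(
                PhantomSpec(
                    flexion_angle=float(angle),
                    pixel_spacing=float(rng.uniform(*spacing_range)),
                    seed=int(rng.integers(2**31)),
                )
            )
    return specs


# ---------------------------------------------------------------------------
# DICOM export (to exercise the DICOM reader)
# ---------------------------------------------------------------------------


def export_dicom_series(volume: CTVolume, out_dir: str | os.PathLike) -> None:
    """Write a CT volume as a single-frame DICOM series (one file per slice)."""
    from pathlib import Path

    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    normal = volume.slice_normal
    iop = list(volume.orientation[:, 0]) + list(volume.orientation[:, 1])
    stored = np.clip(np.round(volume.voxels + 1024.0), 0, 65535).astype(np.uint16)

    for z in range(volume.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = z + 1
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.PixelSpacing = [volume.pixel_spacing, volume.pixel_spacing]
        ds.SliceThickness = volume.slice_distance
        ds.ImageOrientationPatient = [float(v) for v in iop]
        pos = volume.origin + z * volume.slice_distance * normal
        ds.ImagePositionPatient = [float(v) for v in pos]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = stored[z].tobytes()
        ds.save_as(out / f"slice_{z:04d}.dcm", enforce_file_format=True)


def with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    """Copy of ``spec`` with a different noise seed."""
    return replace(spec, seed=seed)
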