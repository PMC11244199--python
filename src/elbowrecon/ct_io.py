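"""CT volume / label-mask data model and file IO.

Conventions
-----------
* Voxel arrays are indexed ``(z, y, x)`` = (slice, row, column), 0-based.
* ``pixel_spacing`` (mm/px) is the isotropic in-plane spacing; anisotropic
  in-plane spacing is rejected rather than averaged.
* Voxel *centers* map to patient coordinates.  The voxel-to-patient affine is

      p = origin + O_col * spacing * x + O_row * spacing * y + n * slice_distance * z

  with ``n = O_col x O_row`` the slice normal (right-handed, DICOM style).

Supported formats: DICOM series (read), NIfTI-1 (read/write volumes and
masks), STL binary and PLY ascii (write meshes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError

_ORTHO_TOL = 1e-6


@dataclass
class CTVolume:
    """A CT intensity volume (HU) plus voxel geometry.

    Attributes
    ----------
    voxels : (nz, ny, nx) float array of Hounsfield units.
    pixel_spacing : in-plane spacing, mm/pixel (isotropic).
    slice_distance : spacing between consecutive slices, mm.
    orientation : (3, 2) direction cosines; column 0 is the image column
        (x) direction, column 1 the row (y) direction, in patient space.
    origin : (3,) mm, patient position of the center of the upper-left
        voxel of the first slice.
    """

    voxels: np.ndarray
    pixel_spacing: float
    slice_distance: float
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    )
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 2:
            raise DataError(
                f"volume must be 3D with at least 2 slices, got shape {self.voxels.shape}"
            )
        if not (self.pixel_spacing > 0 and self.slice_distance > 0):
            raise DataError("pixel_spacing and slice_distance must be positive")
        if self.orientation.shape != (3, 2):
            raise DataError("orientation must be a 3x2 direction-cosine matrix")
        col, row = self.orientation[:, 0], self.orientation[:, 1]
        if (
            abs(np.linalg.norm(col) - 1) > _ORTHO_TOL
            or abs(np.linalg.norm(row) - 1) > _ORTHO_TOL
            or abs(np.dot(col, row)) > _ORTHO_TOL
        ):
            raise DataError("orientation columns must be unit-norm and orthogonal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def slice_normal(self) -> np.ndarray:
        return np.cross(self.orientation[:, 0], self.orientation[:, 1])

    @property
    def affine(self) -> np.ndarray:
        """4x4 affine mapping homogeneous voxel coords (x, y, z, 1) to mm."""
        a = np.eye(4)
        a[:3, 0] = self.orientation[:, 0] * self.pixel_spacing
        a[:3, 1] = self.orientation[:, 1] * self.pixel_spacing
        a[:3, 2] = self.slice_normal * self.slice_distance
        a[:3, 3] = self.origin
        return a

    def voxel_size_mm(self) -> np.ndarray:
        """Physical voxel size as (x, y, z) = (spacing, spacing, slice_distance)."""
        return np.array([self.pixel_spacing, self.pixel_spacing, self.slice_distance])


@dataclass
class LabelMask:
    """Integer label volume aligned with a :class:`CTVolume`.

    0 is background; positive labels map to anatomical names via
    ``label_names``.
    """

    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DataError("label mask must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise DataError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise DataError("labels must be non-negative")

    def binary(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = ("PixelSpacing", "ImageOrientationPatient", "ImagePositionPatient")


def read_dicom_series(path: str | os.PathLike) -> CTVolume:
    """Read a single-frame CT DICOM series from a directory.

    Slices are sorted by their position along the slice normal (file order is
    irrelevant); rescale slope/intercept are applied so voxels are in HU.

    Raises
    ------
    DataError
        If a geometry tag is missing (the message names the file and tag),
        the in-plane shapes are inconsistent, or in-plane spacing is
        anisotropic.
    """
    import pydicom

    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    if not files:
        raise DataError(f"no DICOM files found in {path}")
    datasets = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        for tag in _REQUIRED_TAGS:
            if getattr(ds, tag, None) is None:
                raise DataError(f"file {f.name} is missing required geometry tag {tag}")
        datasets.append(ds)

    ref = datasets[0]
    sp = [float(v) for v in ref.PixelSpacing]  # (row spacing, column spacing)
    if abs(sp[0] - sp[1]) > 1e-6:
        raise DataError(
            f"anisotropic in-plane pixel spacing {sp} is not supported (isotropic assumed)"
        )
    iop = np.array([float(v) for v in ref.ImageOrientationPatient])
    row_dir, col_dir = iop[:3], iop[3:]  # DICOM IOP: row direction then column direction
    # IOP's first triplet is the direction along increasing columns (x), the
    # second along increasing rows (y).
    orientation = np.column_stack([row_dir, col_dir])
    normal = np.cross(orientation[:, 0], orientation[:, 1])

    order = sorted(
        range(len(datasets)),
        key=lambda i: float(np.dot(np.asarray(datasets[i].ImagePositionPatient, float), normal)),
    )
    datasets = [datasets[i] for i in order]

    shape0 = (int(ref.Rows), int(ref.Columns))
    slices = []
    positions = []
    for ds in datasets:
        if (int(ds.Rows), int(ds.Columns)) != shape0:
            raise DataError("inconsistent in-plane shape across the series")
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
        positions.append(np.asarray(ds.ImagePositionPatient, dtype=float))

    proj = [float(np.dot(p, normal)) for p in positions]
    if len(proj) >= 2:
        gaps = np.diff(proj)
        slice_distance = float(np.mean(gaps))
        if slice_distance <= 0 or np.any(np.abs(gaps - slice_distance) > 1e-3):
            raise DataError("slice positions are not uniformly spaced along the normal")
    else:
        slice_distance = float(getattr(ref, "SliceThickness", 1.0))

    return CTVolume(
        voxels=np.stack(slices, axis=0),
        pixel_spacing=sp[0],
        slice_distance=slice_distance,
        orientation=orientation,
        origin=positions[0],
    )


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def _geometry_from_affine(affine: np.ndarray):
    a = np.asarray(affine, dtype=float)
    sx, sy, sz = (np.linalg.norm(a[:3, i]) for i in range(3))
    if abs(sx - sy) > 1e-6:
        raise DataError(
            f"anisotropic in-plane spacing ({sx:.6g} vs {sy:.6g} mm) is not supported"
        )
    orientation = np.column_stack([a[:3, 0] / sx, a[:3, 1] / sy])
    return sx, sz, orientation, a[:3, 3]


def _check_extension(path: Path, allowed: tuple[str, ...], what: str) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in allowed):
        raise DataError(
            f"unsupported extension for {what}: {path.name!r}; supported: {', '.join(allowed)}"
        )


def read_nifti(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI-1 volume; data is stored (x, y, z) on disk, returned (z, y, x)."""
    import nibabel as nib

    path = Path(path)
    _check_extension(path, (".nii", ".nii.gz"), "volume")
    img = nib.load(str(path))
    spacing, slice_distance, orientation, origin = _geometry_from_affine(img.affine)
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
    return CTVolume(data, spacing, slice_distance, orientation, origin)


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    import nibabel as nib

    path = Path(path)
    _check_extension(path, (".nii", ".nii.gz"), "volume")
    img = nib.Nifti1Image(volume.voxels.transpose(2, 1, 0).astype(np.float32), volume.affine)
    nib.save(img, str(path))


def write_mask(mask: LabelMask, geometry: CTVolume, path: str | os.PathLike) -> None:
    """Write a label mask as NIfTI using the parent volume's geometry."""
    import nibabel as nib

    path = Path(path)
    _check_extension(path, (".nii", ".nii.gz"), "mask")
    if mask.labels.shape != geometry.shape:
        raise DataError(
            f"mask shape {mask.labels.shape} does not match volume shape {geometry.shape}"
        )
    img = nib.Nifti1Image(mask.labels.transpose(2, 1, 0).astype(np.int16), geometry.affine)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike, label_names: dict[int, str] | None = None) -> LabelMask:
    import nibabel as nib

    path = Path(path)
    _check_extension(path, (".nii", ".nii.gz"), "mask")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return LabelMask(np.rint(data).astype(np.int16).transpose(2, 1, 0), label_names or {})


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------


def write_mesh(mesh, path: str | os.PathLike) -> None:
    """Write a surface mesh as binary STL or ascii PLY (by extension)."""
    import trimesh

    path = Path(path)
    _check_extension(path, (".stl", ".ply"), "mesh")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if path.suffix.lower() == ".stl":
        tm.export(str(path), file_type="stl")
    else:
        tm.export(str(path), file_type="ply", encoding="ascii")


def read_mesh(path: str | os.PathLike):
    """Read an STL/PLY mesh back as a :class:`~elbowrecon.reconstruction.SurfaceMesh`."""
    import trimesh

    from .reconstruction import SurfaceMesh

    path = Path(path)
    _check_extension(path, (".stl", ".ply"), "mesh")
    tm = trimesh.load(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))
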