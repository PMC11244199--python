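"""Slice-by-slice promptable segmentation behind a pluggable backend.

The deep promptable model (and its training) is deliberately outside this
package: any segmenter satisfying :class:`SegmenterBackend` — given a 2D
slice and a prompt box, return a deterministic binary mask that is empty
outside the box — can drive the pipeline.  The package ships
:class:`ReferenceBackend`, a deterministic threshold-and-morphology
segmenter, so the whole pipeline is runnable and testable end to end; an
adapter contract for an external promptable checkpoint is described by
:class:`PromptableAdapterConfig`.

This module also assembles training samples (image, expert mask, jittered
box) for fine-tuning an external promptable model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage import morphology

from .ct_io import CTVolume, LabelMask
from .errors import DataError, StageError
from .prompt_boxes import PromptBox, jitter_box, narrow_box
from .recognition import ConnectedComponent, connected_components


@runtime_checkable
class SegmenterBackend(Protocol):
    """Contract: deterministic per-slice, per-box binary segmentation."""

    def segment(self, image: np.ndarray, box: PromptBox) -> np.ndarray:
        """Return a binary mask of ``image``'s shape, empty outside ``box``."""
        ...


@dataclass
class ReferenceBackend:
    """Deterministic threshold-and-morphology segmenter.

    Within the prompt box: threshold at ``hu_low`` (lower than the
    recognition threshold so low-density bone ends and marrow are captured),
    morphological closing with a disk of ``closing_radius`` px, and removal
    of components smaller than ``min_area`` px.  Everything outside the box
    is background.
    """

    hu_low: float = 150.0
    closing_radius: int = 2
    min_area: int = 5

    def segment(self, image: np.ndarray, box: PromptBox) -> np.ndarray:
        image = np.asarray(image)
        if image.ndim != 2:
            raise DataError("backend expects a 2D slice")
        ny, nx = image.shape
        if not (0 <= box.x_min <= box.x_max < nx and 0 <= box.y_min <= box.y_max < ny):
            raise DataError(f"box {box} exceeds image shape {image.shape}")
        rows, cols = box.as_slices()
        crop = image[rows, cols] >= self.hu_low
        if self.closing_radius > 0:
            # edge-pad so closing does not erode foreground at the box border
            r = self.closing_radius
            padded = np.pad(crop, r, mode="edge")
            padded = ndimage.binary_closing(padded, structure=morphology.disk(r))
            crop = padded[r:-r, r:-r]
        if self.min_area > 1 and crop.any():
            labels, n = ndimage.label(crop, structure=np.ones((3, 3), bool))
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            crop = (counts >= self.min_area)[labels]
        out = np.zeros(image.shape, dtype=bool)
        out[rows, cols] = crop
        return out


@dataclass
class PromptableAdapterConfig:
    """Input contract for wiring an external promptable checkpoint.

    The slice is windowed to ``[window_low, window_high]`` HU and linearly
    normalized to [0, 1]; boxes are handed over in corner-point convention
    (x_min, y_min, x_max, y_max), half-open per ``box_exclusive_max``.  The
    windowing is configurable because no canonical choice exists for elbow
    CT; the default is a wide bone window.
    """

    window_low: float = -500.0
    window_high: float = 1500.0
    box_exclusive_max: bool = True

    def normalize(self, image: np.ndarray) -> np.ndarray:
        lo, hi = self.window_low, self.window_high
        return np.clip((np.asarray(image, float) - lo) / (hi - lo), 0.0, 1.0)

    def box_corners(self, box: PromptBox) -> tuple[int, int, int, int]:
        off = 1 if self.box_exclusive_max else 0
        return box.x_min, box.y_min, box.x_max + off, box.y_max + off

    @classmethod
    def from_yaml(cls, path) -> "PromptableAdapterConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


def _assert_within_box(mask: np.ndarray, box: PromptBox, bone: str) -> None:
    outside = mask.copy()
    rows, cols = box.as_slices()
    outside[rows, cols] = False
    if outside.any():
        raise StageError(
            "segment",
            f"backend produced foreground outside the prompt box (bone {bone}, slice {box.z})",
        )


def segment_volume(
    volume: CTVolume,
    boxes: dict[str, list[PromptBox]],
    backend: SegmenterBackend,
) -> dict[str, np.ndarray]:
    """Segment each bone slice by slice from its expanded prompt boxes.

    Returns one binary volume per bone; slices without a box stay empty.
    Backend masks are asserted to stay inside their box on every call.
    """
    out = {bone: np.zeros(volume.shape, dtype=bool) for bone in boxes}
    for bone, per_bone in boxes.items():
        for box in per_bone:
            if not 0 <= box.z < volume.shape[0]:
                raise StageError("segment", f"box slice {box.z} outside volume (bone {bone})")
            try:
                mask = np.asarray(backend.segment(volume.voxels[box.z], box), dtype=bool)
            except StageError:
                raise
            except Exception as exc:  # surface bone + slice on any backend failure
                raise StageError(
                    "segment", f"backend failed on bone {bone}, slice {box.z}: {exc}"
                ) from exc
            if mask.shape != volume.shape[1:]:
                raise StageError(
                    "segment",
                    f"backend mask shape {mask.shape} != slice shape {volume.shape[1:]} "
                    f"(bone {bone}, slice {box.z})",
                )
            _assert_within_box(mask, box, bone)
            out[bone][box.z] |= mask
    return out


# ---------------------------------------------------------------------------
# Training-sample assembly
# ---------------------------------------------------------------------------


@dataclass
class TrainingSample:
    """One (image slice, expert mask, jittered prompt box) triple."""

    image: np.ndarray
    label: np.ndarray
    box: PromptBox

    def __post_init__(self):
        if self.image.shape != self.label.shape:
            raise DataError("image and label shapes differ")
        rows, cols = self.box.as_slices()
        if not self.label[rows, cols].any():
            raise DataError("label is empty within the prompt box")


def build_training_set(
    volumes: list[CTVolume],
    gt_masks: list[LabelMask],
    rng: np.random.Generator,
    max_expand: int = 30,
) -> list[TrainingSample]:
    """One sample per (slice, bone) with nonempty expert mask.

    The prompt box is the tight box of the expert mask on that slice,
    jittered outward by up to ``max_expand`` px per side (seeded ``rng``).
    """
    if len(volumes) != len(gt_masks):
        raise DataError("volumes and gt_masks must pair up")
    samples: list[TrainingSample] = []
    for vol, gt in zip(volumes, gt_masks):
        if gt.labels.shape != vol.shape:
            raise DataError(
                f"GT shape {gt.labels.shape} does not match volume shape {vol.shape}"
            )
        for label in sorted(set(np.unique(gt.labels)) - {0}):
            binary = gt.labels == int(label)
            zz, yy, xx = np.nonzero(binary)
            comp = ConnectedComponent(
                id=int(label),
                voxel_indices=np.column_stack([zz, yy, xx]).astype(np.int64),
                points_mm=np.empty((len(zz), 3)),
            )
            bone = gt.label_names.get(int(label), f"label_{label}")
            for z in sorted(set(zz.tolist())):
                nb = narrow_box(comp, z)
                assert nb is not None
                box = jitter_box(nb, rng, vol.shape[1:], max_expand)
                box = PromptBox(**{**asdict(box), "bone": bone})
                samples.append(
                    TrainingSample(image=vol.voxels[z], label=binary[z], box=box)
                )
    return samples


def export_training_set(samples: list[TrainingSample], out_dir) -> None:
    """Write samples as 16-bit PNG image/mask pairs plus a JSON box manifest."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(samples):
        img16 = np.clip(s.image + 1024.0, 0, 65535).astype(np.uint16)  # HU + 1024 offset
        Image.fromarray(img16).save(out_dir / f"sample_{i:05d}_image.png")
        Image.fromarray((s.label.astype(np.uint16)) * 65535).save(
            out_dir / f"sample_{i:05d}_mask.png"
        )
        manifest.append({"index": i, **asdict(s.box)})
    (out_dir / "boxes.json").write_text(json.dumps(manifest, indent=2))


__all__ = [
    "SegmenterBackend",
    "ReferenceBackend",
    "PromptableAdapterConfig",
    "segment_volume",
    "TrainingSample",
    "build_training_set",
    "export_training_set",
    "connected_components",
]
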