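"""Per-slice prompt-box generation for promptable segmentation.

A *narrow* box is the tight axis-aligned bounding rectangle of a recognized
component's voxels projected onto one slice; an *expanded* box moves every
side outward by ``d`` pixels and clips to the image.  Following the values
validated for elbow CT, the default expansion is 20 px on slices near the
bone ends (where low bone-mineral density leaves the recognized mask
incomplete) and 10 px along the shaft.  Boxes use inclusive pixel indices in
the (x = column, y = row) convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import DataError
from .recognition import ConnectedComponent, RecognitionResult


@dataclass(frozen=True)
class PromptBox:
    """Axis-aligned inclusive-pixel rectangle on one slice."""

    z: int
    bone: str
    x_min: int
    x_max: int
    y_min: int
    y_max: int
    kind: str = "narrow"  # "narrow" | "expanded"
    d: int = 0

    def __post_init__(self):
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise DataError(f"degenerate box: {self}")

    def contains(self, other: "PromptBox") -> bool:
        return (
            self.x_min <= other.x_min
            and self.x_max >= other.x_max
            and self.y_min <= other.y_min
            and self.y_max >= other.y_max
        )

    def as_slices(self) -> tuple[slice, slice]:
        """(row, column) slices selecting the box region of a 2D image."""
        return slice(self.y_min, self.y_max + 1), slice(self.x_min, self.x_max + 1)


def narrow_box(component: ConnectedComponent, slice_index: int) -> PromptBox | None:
    """Tight bounding box of the component's voxels on ``slice_index``.

    Returns None if the component has no voxel on that slice.  A bone with
    several disjoint in-slice regions still gets one box covering them all.
    """
    idx = component.voxel_indices
    on = idx[idx[:, 0] == slice_index]
    if len(on) == 0:
        return None
    return PromptBox(
        z=int(slice_index),
        bone=f"component_{component.id}",
        x_min=int(on[:, 2].min()),
        x_max=int(on[:, 2].max()),
        y_min=int(on[:, 1].min()),
        y_max=int(on[:, 1].max()),
    )


def expand_box(box: PromptBox, d: int, image_shape: tuple[int, int]) -> PromptBox:
    """Move each side outward by ``d`` px, clipped to the (ny, nx) image."""
    if d < 0:
        raise DataError("expansion d must be >= 0")
    ny, nx = image_shape
    return replace(
        box,
        x_min=max(0, box.x_min - d),
        x_max=min(nx - 1, box.x_max + d),
        y_min=max(0, box.y_min - d),
        y_max=min(ny - 1, box.y_max + d),
        kind="expanded",
        d=int(d),
    )


def classify_end_or_shaft(
    component: ConnectedComponent, slice_index: int, end_fraction: float = 0.2
) -> str:
    """Label a slice "end" or "shaft" by its position in the bone's slice range.

    A slice within ``end_fraction`` of either extreme of the component's
    slice span counts as an end; a single-slice bone is all end.
    """
    z_lo, z_hi = component.slice_range()
    span = z_hi - z_lo
    if span == 0:
        return "end"
    margin = end_fraction * span
    if slice_index - z_lo < margin or z_hi - slice_index < margin:
        return "end"
    return "shaft"


def jitter_box(
    box: PromptBox,
    rng: np.random.Generator,
    image_shape: tuple[int, int],
    max_expand: int = 30,
) -> PromptBox:
    """Randomly expand each side outward by an independent uniform integer
    on [0, max_expand]; used when assembling training samples so a model
    does not over-rely on exact box boundaries.  Deterministic given ``rng``.
    """
    if max_expand == 0:
        return replace(box, kind="expanded", d=0)
    lo_x, hi_x, lo_y, hi_y = rng.integers(0, max_expand + 1, size=4)
    ny, nx = image_shape
    return replace(
        box,
        x_min=max(0, box.x_min - int(lo_x)),
        x_max=min(nx - 1, box.x_max + int(hi_x)),
        y_min=max(0, box.y_min - int(lo_y)),
        y_max=min(ny - 1, box.y_max + int(hi_y)),
        kind="expanded",
        d=int(max_expand),
    )


def generate_boxes(
    result: RecognitionResult,
    image_shape: tuple[int, int],
    d_end: int = 20,
    d_shaft: int = 10,
    end_fraction: float = 0.2,
) -> dict[str, list[PromptBox]]:
    """Expanded prompt boxes for every bone and every slice where it appears."""
    boxes: dict[str, list[PromptBox]] = {}
    for bone in ("humerus", "ulna", "radius"):
        comp = result.bone(bone)
        z_lo, z_hi = comp.slice_range()
        per_bone = []
        for z in range(z_lo, z_hi + 1):
            nb = narrow_box(comp, z)
            if nb is None:
                continue
            nb = replace(nb, bone=bone)
            d = d_end if classify_end_or_shaft(comp, z, end_fraction) == "end" else d_shaft
            per_bone.append(expand_box(nb, d, image_shape))
        boxes[bone] = per_bone
    return boxes


# ---------------------------------------------------------------------------
# JSONL export
# ---------------------------------------------------------------------------


def boxes_to_jsonl(boxes: dict[str, list[PromptBox]], path) -> None:
    with Path(path).open("w") as fh:
        for bone in boxes:
            for box in boxes[bone]:
                fh.write(json.dumps(asdict(box)) + "\n")


def boxes_from_jsonl(path) -> dict[str, list[PromptBox]]:
    boxes: dict[str, list[PromptBox]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        box = PromptBox(**json.loads(line))
        boxes.setdefault(box.bone, []).append(box)
    return boxes


def _iter_boxes(boxes: dict[str, Iterable[PromptBox]]):
    for bone, per_bone in boxes.items():
        for box in per_bone:
            yield bone, box
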