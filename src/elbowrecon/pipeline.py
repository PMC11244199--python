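"""End-to-end orchestration: recognition → boxes → segmentation → refinement
→ reconstruction, with artifacts written to an output directory.

Every run is reproducible from its logged config + seed; with the
deterministic reference backend reruns are bitwise identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ct_io, mask_refine, metrics, prompt_boxes, reconstruction, segmentation
from .config import PipelineConfig
from .ct_io import CTVolume, LabelMask
from .errors import DataError, StageError
from .recognition import BONE_LABEL_VALUES, RecognitionResult, recognize
from .segmentation import SegmenterBackend

logger = logging.getLogger(__name__)

BONES = ("humerus", "ulna", "radius")


@dataclass
class PipelineProducts:
    """In-memory results of a full pipeline run."""

    recognition: RecognitionResult
    boxes: dict[str, list[prompt_boxes.PromptBox]]
    raw_masks: dict[str, np.ndarray]
    refined_masks: dict[str, np.ndarray]
    refinement_report: mask_refine.RefinementReport
    meshes: dict[str, reconstruction.SurfaceMesh]
    metrics_report: dict | None = None
    timings: dict[str, float] = field(default_factory=dict)


def load_input(path: str | Path) -> CTVolume:
    """Load a CT volume from a DICOM directory or a NIfTI file."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input path does not exist: {path}")
    if path.is_dir():
        return ct_io.read_dicom_series(path)
    return ct_io.read_nifti(path)


def run_pipeline(
    volume: CTVolume,
    config: PipelineConfig | None = None,
    backend: SegmenterBackend | None = None,
    gt: LabelMask | None = None,
) -> PipelineProducts:
    """Run every stage on an in-memory volume; evaluate against GT if given."""
    config = config or PipelineConfig()
    backend = backend or segmentation.ReferenceBackend(
        hu_low=config.backend.hu_low,
        closing_radius=config.backend.closing_radius,
        min_area=config.backend.min_area,
    )
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    recog = recognize(volume, config.recognition)
    timings["recognize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    boxes = prompt_boxes.generate_boxes(
        recog,
        volume.shape[1:],
        d_end=config.boxes.d_end,
        d_shaft=config.boxes.d_shaft,
        end_fraction=config.boxes.end_fraction,
    )
    timings["boxes"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    raw = segmentation.segment_volume(volume, boxes, backend)
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    spacing = (volume.pixel_spacing, volume.pixel_spacing, volume.slice_distance)
    refined, report = mask_refine.refine_volume(
        raw,
        recog,
        fill_3d=config.refine.fill_3d,
        resolve_overlaps=config.refine.resolve_overlaps,
        spacing=spacing,
    )
    timings["refine"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    meshes = {
        bone: reconstruction.reconstruct_bone(
            refined[bone], volume, config.reconstruction.smooth_iters, bone=bone
        )
        for bone in BONES
        if refined[bone].any()
    }
    timings["reconstruct"] = time.perf_counter() - t0

    report_dict = None
    if gt is not None:
        report_dict = evaluate_masks(refined, gt)

    return PipelineProducts(
        recognition=recog,
        boxes=boxes,
        raw_masks=raw,
        refined_masks=refined,
        refinement_report=report,
        meshes=meshes,
        metrics_report=report_dict,
        timings=timings,
    )


def evaluate_masks(per_bone: dict[str, np.ndarray], gt: LabelMask) -> dict:
    """Volume IoU/Dice per bone plus per-slice IoU summaries vs a label mask."""
    name_to_label = {v: k for k, v in gt.label_names.items()}
    out: dict = {}
    for bone, mask in per_bone.items():
        label = name_to_label.get(bone, BONE_LABEL_VALUES.get(bone))
        if label is None:
            continue
        gt_bin = gt.labels == label
        curve = metrics.per_slice_iou(mask, gt_bin)
        out[bone] = {
            "volume_iou": metrics.iou(mask, gt_bin),
            "volume_dice": metrics.dice(mask, gt_bin),
            "per_slice_iou": metrics.summarize(list(curve.values())) if curve else None,
        }
    return out


def labels_from_masks(per_bone: dict[str, np.ndarray]) -> LabelMask:
    shape = next(iter(per_bone.values())).shape
    labels = np.zeros(shape, dtype=np.int16)
    for bone, value in BONE_LABEL_VALUES.items():
        if bone in per_bone:
            labels[per_bone[bone]] = value
    return LabelMask(labels, {v: k for k, v in BONE_LABEL_VALUES.items()})


def run(
    input_path: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
    gt_path: str | Path | None = None,
    backend: SegmenterBackend | None = None,
) -> PipelineProducts:
    """Run the pipeline on a file/directory input and write all artifacts.

    Writes recognition JSON, box JSONL, a refined label NIfTI, three STL
    meshes, a metrics report when GT is given, and a run log carrying the
    config hash and seed.  Partial artifacts are retained if a stage fails.
    """
    config = config or PipelineConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    volume = load_input(input_path)
    gt = ct_io.read_mask(gt_path, dict({v: k for k, v in BONE_LABEL_VALUES.items()})) if gt_path else None

    log: dict = {
        "input": str(input_path),
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": [],
    }
    log_path = out / "run_log.json"
    try:
        products = run_pipeline(volume, config, backend=backend, gt=gt)
    except StageError as exc:
        log["error"] = {"stage": exc.stage, "message": str(exc)}
        log_path.write_text(json.dumps(log, indent=2))
        raise

    products.recognition.save_json(out / "recognition.json")
    prompt_boxes.boxes_to_jsonl(products.boxes, out / "boxes.jsonl")
    ct_io.write_mask(labels_from_masks(products.refined_masks), volume, out / "labels.nii")
    for bone, mesh in products.meshes.items():
        ct_io.write_mesh(mesh, out / f"{bone}.stl")
        mesh.save_metadata(out / f"{bone}_mesh.json", bone)
    if products.metrics_report is not None:
        (out / "metrics.json").write_text(json.dumps(products.metrics_report, indent=2))

    log["stages"] = [
        {"stage": k, "seconds": round(v, 3)} for k, v in products.timings.items()
    ]
    log["boxes_per_bone"] = {b: len(v) for b, v in products.boxes.items()}
    log["mesh_counts"] = {b: m.metadata() for b, m in products.meshes.items()}
    log_path.write_text(json.dumps(log, indent=2))
    return products
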