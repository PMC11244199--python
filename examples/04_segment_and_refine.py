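"""Segment each bone slice-by-slice, then correct the masks.

Near the joint, a bone's expanded prompt box also covers its neighbor, so
the raw prediction can contain foreign-bone pixels; reclassification keeps
only components touching the bone's own recognized voxels, and hole filling
restores the marrow cavity the backend's threshold misses.
"""

from elbowrecon import mask_refine, metrics, phantom, prompt_boxes, segmentation
from elbowrecon.recognition import recognize

result = phantom.generate(phantom.PhantomSpec(flexion_angle=120.0, seed=7))
vol, gt = result.volume, result.labels

recog = recognize(vol)
boxes = prompt_boxes.generate_boxes(recog, vol.shape[1:])
raw = segmentation.segment_volume(vol, boxes, segmentation.ReferenceBackend())
spacing = (vol.pixel_spacing, vol.pixel_spacing, vol.slice_distance)
refined, report = mask_refine.refine_volume(raw, recog, spacing=spacing)

print("volume IoU against ground truth (raw prediction -> after refinement):")
for bone, value in (("humerus", 1), ("ulna", 2), ("radius", 3)):
    gt_bin = gt.labels == value
    before = metrics.iou(raw[bone], gt_bin)
    after = metrics.iou(refined[bone], gt_bin)
    print(f"  {bone:8s}: {before:.3f} -> {after:.3f}")
print(
    f"overlap voxels claimed by two bones and reassigned: "
    f"{report.overlap_voxels_reassigned}"
)
# The jump comes from filled marrow cavities plus removal of neighbor-bone
# pixels that the expanded boxes unavoidably include near the trochlea.
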