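"""Generate per-slice prompt boxes for each recognized bone.

A narrow box is the tight projection of the recognized voxels on a slice;
the expanded box grows it by 20 px near the bone ends (where low bone
density leaves the recognized mask incomplete) and 10 px along the shaft.
"""

from collections import Counter

from elbowrecon import phantom, prompt_boxes
from elbowrecon.recognition import recognize

result = phantom.generate(phantom.PhantomSpec(flexion_angle=120.0, seed=7))
recog = recognize(result.volume)
boxes = prompt_boxes.generate_boxes(recog, result.volume.shape[1:])

for bone, per_bone in boxes.items():
    by_d = Counter(b.d for b in per_bone)
    print(f"{bone:8s}: {len(per_bone):3d} slices with boxes, expansion counts {dict(by_d)}")

example = boxes["humerus"][len(boxes["humerus"]) // 2]
print(
    f"example humerus box on slice {example.z}: "
    f"x [{example.x_min}, {example.x_max}], y [{example.y_min}, {example.y_max}], "
    f"expanded by d={example.d} px"
)
prompt_boxes.boxes_to_jsonl(boxes, "boxes.jsonl")
print("wrote boxes.jsonl (one JSON box per line, grouped by bone)")
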