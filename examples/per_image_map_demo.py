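"""Per-image mAP_50:95 on hand-built detections.

Shows how the COCO-style protocol behaves on a single image: perfect
detections score 1, a detection overlapping its ground truth at IoU 0.60
passes exactly the 0.50/0.55/0.60 thresholds (mAP 0.30), and a false
positive ranked above a true positive drags AP down.
"""

from uweval.det_io import Box
from uweval.perimage import per_image_map5095

gts = [(Box(0, 0, 10, 10), 1)]

perfect = [(Box(0, 0, 10, 10), 1, 1.0)]
score = per_image_map5095(perfect, gts, image_id=0, variant_id=0)
print(f"identity detection:      mAP_50:95 = {score.map5095:.2f}")

# intersection 60, union 100 -> IoU exactly 0.60
at_060 = [(Box(0, 0, 10, 6), 1, 0.9)]
score = per_image_map5095(at_060, gts, 0, 0)
print(f"detection at IoU 0.60:   mAP_50:95 = {score.map5095:.2f}  "
      f"(AP per threshold: {[round(v, 2) for v in score.per_threshold]})")

with_fp = [
    (Box(40, 40, 10, 10), 1, 0.95),   # confident false positive, ranked first
    (Box(0, 0, 10, 10), 1, 0.80),     # exact match, ranked second
]
score = per_image_map5095(with_fp, gts, 0, 0)
print(f"FP above the TP:         mAP_50:95 = {score.map5095:.3f}")

no_gt = per_image_map5095(perfect, [], 0, 0)
print(f"image without ground truth: defined = {no_gt.defined} (excluded from set means)")
print("\nThe per-image score isolates one image's PR curve, so enhancement")
print("effects can be attributed image by image instead of dataset-wide.")
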