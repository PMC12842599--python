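"""Independent straight-line reference for the COCO detection protocol.

Implements greedy matching, 101-point interpolated AP, per-image mAP_50:95
and pooled dataset mAP with explicit loops over plain tuples, sharing no code
with ``uweval``. Boxes are (x, y, w, h) tuples; detections are
(x, y, w, h, score); the interpolated precision at recall r is computed
directly as max{precision_i : recall_i >= r}.
"""

import math

IOU_THRS = [0.50 + 0.05 * k for k in range(10)]
# the COCO recall grid: k * 0.01 in double precision with an exact endpoint
# (the protocol's reference tooling builds it the same way)
REC_THRS = [k * 0.01 for k in range(100)] + [1.0]


def ref_iou(a, b) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = min(ax + aw, bx + bw) - max(ax, bx)
    iy = min(ay + ah, by + bh) - max(ay, by)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (aw * ah + bw * bh - inter)


def ref_match(dets, gts, thr):
    """Greedy matching; returns tp flags in descending-confidence order."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][4], i))
    used = [False] * len(gts)
    tp = []
    for i in order:
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if used[j]:
                continue
            v = ref_iou(dets[i][:4], gt)
            if v >= thr and v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            used[best_j] = True
            tp.append(True)
        else:
            tp.append(False)
    return tp


def ref_ap_from_tp(tp, n_gt):
    if n_gt <= 0:
        raise ValueError("undefined without ground truth")
    if not tp:
        return 0.0
    recalls, precisions = [], []
    n_tp = n_fp = 0
    for flag in tp:
        if flag:
            n_tp += 1
        else:
            n_fp += 1
        recalls.append(n_tp / n_gt)
        precisions.append(n_tp / (n_tp + n_fp))
    total = 0.0
    for r in REC_THRS:
        best = 0.0
        for rec, prec in zip(recalls, precisions):
            if rec >= r and prec > best:
                best = prec
        total += best
    return total / len(REC_THRS)


def ref_ap(dets, gts, thr):
    return ref_ap_from_tp(ref_match(dets, gts, thr), len(gts))


def ref_per_image_map5095(dets, gts):
    """dets: list of (x, y, w, h, category, score); gts: (x, y, w, h, category).

    Returns None for an image without ground truth.
    """
    if not gts:
        return None
    categories = sorted({g[4] for g in gts})
    total = 0.0
    for thr in IOU_THRS:
        cat_sum = 0.0
        for cat in categories:
            cgts = [g[:4] for g in gts if g[4] == cat]
            cdets = [(d[0], d[1], d[2], d[3], d[5]) for d in dets if d[4] == cat]
            cat_sum += ref_ap(cdets, cgts, thr)
        total += cat_sum / len(categories)
    return total / len(IOU_THRS)


def ref_dataset_map(dets_by_image, gts_by_image):
    """Pooled COCO-style dataset mAP.

    ``dets_by_image``: {image_id: [(x, y, w, h, category, score), ...]};
    ``gts_by_image``: {image_id: [(x, y, w, h, category), ...]}.
    Returns (map50, map5095).
    """
    categories = sorted({g[4] for gts in gts_by_image.values() for g in gts})
    image_ids = sorted(gts_by_image)
    ap_50, ap_all = [], []
    for cat in categories:
        n_gt = sum(1 for gts in gts_by_image.values() for g in gts if g[4] == cat)
        per_thr = []
        for thr in IOU_THRS:
            entries = []  # (score, input_rank, tp) pooled over images
            rank = 0
            for image_id in image_ids:
                cgts = [g[:4] for g in gts_by_image[image_id] if g[4] == cat]
                cdets = [
                    (d[0], d[1], d[2], d[3], d[5])
                    for d in dets_by_image.get(image_id, [])
                    if d[4] == cat
                ]
                tp = ref_match(cdets, cgts, thr)
                scores = sorted((d[4] for d in cdets), reverse=True)
                for s, flag in zip(scores, tp):
                    entries.append((s, rank, flag))
                    rank += 1
            entries.sort(key=lambda e: (-e[0], e[1]))
            per_thr.append(ref_ap_from_tp([e[2] for e in entries], n_gt))
        ap_all.append(sum(per_thr) / len(per_thr))
        ap_50.append(per_thr[0])
    return sum(ap_50) / len(ap_50), sum(ap_all) / len(ap_all)
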