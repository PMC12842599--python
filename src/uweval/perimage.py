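"""Per-image and dataset-level COCO-style mAP at IoU 0.50:0.95.

The per-image protocol scores every (image, variant) pair on its own: a
precision-recall curve is built from only that image's predictions and
ground-truth boxes, AP is computed at the ten IoU thresholds 0.50, 0.55, ...,
0.95, averaged over the categories present in the image's ground truth, and
the ten threshold values are averaged into a single per-image mAP_50:95.

Matching is greedy in descending confidence: each detection is matched to the
unmatched ground-truth box of its category with the highest IoU at or above
the threshold, otherwise it is a false positive; each ground-truth box can be
matched at most once. Equal confidences keep input-file order (stable sort),
so results are reproducible bit for bit.

The PR-curve area uses COCO's 101-point interpolated precision by default; an
all-point trapezoidal variant is available via ``interpolation="trapezoid"``
for sensitivity checks.

Category-averaging convention at image level: only categories present in the
image's ground truth contribute; a category with ground truth but no
detections contributes AP 0, while detections of a category absent from the
image's ground truth are ignored for that image. Images with zero
ground-truth boxes have no recall axis, so their per-image score is undefined
(``defined=False``) and they are excluded from set means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from uweval.det_io import Box, DetectionSet, GroundTruthSet

__all__ = [
    "IOU_THRESHOLDS",
    "RECALL_THRESHOLDS",
    "PerImageScore",
    "ScoreMatrix",
    "iou",
    "match_image",
    "average_precision",
    "per_image_ap",
    "per_image_map5095",
    "dataset_map",
    "score_matrix",
]

#: The ten IoU thresholds 0.50:0.05:0.95 of the COCO protocol.
IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
#: The 101 recall points of COCO's interpolated AP.
RECALL_THRESHOLDS = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class PerImageScore:
    """mAP_50:95 of one (image, variant) pair with its breakdowns.

    ``map5095`` is the mean of ``per_threshold`` (each entry already averaged
    over the categories present in the image's ground truth). ``defined`` is
    False when the image has no ground-truth boxes; such scores carry NaN and
    are excluded from set means.
    """

    image_id: int
    variant_id: int
    map5095: float
    per_threshold: tuple[float, ...]
    per_category: dict[int, tuple[float, ...]]
    defined: bool = True


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint boxes."""
    ix = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
    iy = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    # guard against roundoff in (x + w) - x pushing the ratio past 1
    return min(inter / (a.area + b.area - inter), 1.0)


def _sort_by_confidence(dets):
    """Stable descending-confidence order (ties keep input order)."""
    scores = np.array([s for _, s in dets], dtype=float)
    return np.argsort(-scores, kind="stable")


def match_image(dets, gts, iou_thr: float):
    """Greedy single-image, single-category matching.

    Parameters
    ----------
    dets : list of (Box, score)
    gts : list of Box
    iou_thr : float

    Returns
    -------
    tp : numpy bool array aligned to descending-confidence order
    order : int array mapping that order back to input positions
    fn : number of ground-truth boxes left unmatched
    """
    order = _sort_by_confidence(dets)
    matched = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for rank, det_idx in enumerate(order):
        box = dets[det_idx][0]
        best_iou, best_gt = 0.0, -1
        for gt_idx, gt_box in enumerate(gts):
            if matched[gt_idx]:
                continue
            value = iou(box, gt_box)
            if value >= iou_thr and value > best_iou:
                best_iou, best_gt = value, gt_idx
        if best_gt >= 0:
            matched[best_gt] = True
            tp[rank] = True
    return tp, order, int(len(gts) - matched.sum())


def average_precision(tp: np.ndarray, n_gt: int, interpolation: str = "coco101") -> float:
    """AP from confidence-ordered TP labels and the ground-truth count.

    ``"coco101"`` evaluates the monotone precision envelope at 101 equally
    spaced recall points; ``"trapezoid"`` integrates the raw PR polyline.
    """
    if n_gt <= 0:
        raise ValueError("average_precision is undefined without ground-truth boxes")
    tp = np.asarray(tp, dtype=bool)
    if tp.size == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    if interpolation == "coco101":
        # monotone non-increasing envelope from the right, as in COCO
        envelope = np.maximum.accumulate(precision[::-1])[::-1]
        idx = np.searchsorted(recall, RECALL_THRESHOLDS, side="left")
        q = np.where(idx < recall.size, envelope[np.minimum(idx, recall.size - 1)], 0.0)
        return float(q.mean())
    if interpolation == "trapezoid":
        r = np.concatenate([[0.0], recall])
        p = np.concatenate([[precision[0]], precision])
        return float(np.trapezoid(p, r))
    raise ValueError(f"unknown interpolation mode {interpolation!r}")


def per_image_ap(dets, gts, iou_thr: float, interpolation: str = "coco101") -> float:
    """Single-image, single-category AP at one IoU threshold.

    ``dets`` is a list of (Box, score); ``gts`` a nonempty list of Box.
    """
    if not gts:
        raise ValueError("per-image AP is undefined for a category with no ground truth")
    tp, _, _ = match_image(dets, gts, iou_thr)
    return average_precision(tp, len(gts), interpolation)


def per_image_map5095(dets, gts, image_id, variant_id: int,
                      interpolation: str = "coco101") -> PerImageScore:
    """Per-image mAP_50:95 across all categories present in the ground truth.

    ``dets`` is a list of (Box, category_id, score); ``gts`` a list of
    (Box, category_id). Returns ``defined=False`` with NaN scores when the
    image has no ground-truth boxes.
    """
    if not gts:
        nan10 = tuple([float("nan")] * len(IOU_THRESHOLDS))
        return PerImageScore(
            image_id=image_id, variant_id=variant_id, map5095=float("nan"),
            per_threshold=nan10, per_category={}, defined=False,
        )
    categories = sorted({cat for _, cat in gts})
    per_category: dict[int, tuple[float, ...]] = {}
    for cat in categories:
        cat_gts = [box for box, c in gts if c == cat]
        cat_dets = [(box, score) for box, c, score in dets if c == cat]
        per_category[cat] = tuple(
            per_image_ap(cat_dets, cat_gts, thr, interpolation) for thr in IOU_THRESHOLDS
        )
    ap_matrix = np.array([per_category[c] for c in categories])
    per_threshold = ap_matrix.mean(axis=0)
    return PerImageScore(
        image_id=image_id,
        variant_id=variant_id,
        map5095=float(per_threshold.mean()),
        per_threshold=tuple(float(v) for v in per_threshold),
        per_category=per_category,
        defined=True,
    )


def dataset_map(dets: DetectionSet, gts: GroundTruthSet,
                interpolation: str = "coco101") -> dict[str, float]:
    """Conventional pooled COCO-style dataset evaluation.

    Matching is still per image, but the PR curve for each category pools the
    confidence-ordered detections of all images. Categories without any
    ground-truth box are skipped. Returns ``{"map50": ..., "map5095": ...}``.
    """
    cat_gt_count = {cat: 0 for cat in gts.categories}
    for boxes in gts.boxes.values():
        for _, cat in boxes:
            cat_gt_count[cat] += 1
    active = [cat for cat, n in cat_gt_count.items() if n > 0]
    if not active:
        raise ValueError("dataset has no ground-truth boxes")
    ap = np.zeros((len(active), len(IOU_THRESHOLDS)))
    for ci, cat in enumerate(active):
        for ti, thr in enumerate(IOU_THRESHOLDS):
            scores_all, tp_all = [], []
            for image_id in gts.image_ids:
                cat_gts = [box for box, c in gts.boxes[image_id] if c == cat]
                cat_dets = [(box, s) for box, c, s in dets.for_image(image_id) if c == cat]
                if not cat_dets:
                    continue
                tp, order, _ = match_image(cat_dets, cat_gts, thr)
                scores_all.append(np.array([cat_dets[i][1] for i in order]))
                tp_all.append(tp)
            if scores_all:
                scores = np.concatenate(scores_all)
                tp = np.concatenate(tp_all)
                pooled = np.argsort(-scores, kind="stable")
                ap[ci, ti] = average_precision(tp[pooled], cat_gt_count[cat], interpolation)
    thr50 = IOU_THRESHOLDS.index(0.5)
    return {"map50": float(ap[:, thr50].mean()), "map5095": float(ap.mean())}


@dataclass
class ScoreMatrix:
    """N x (V+1) matrix of per-image mAP_50:95 values.

    ``values`` is a DataFrame indexed by image_id with one column per
    variant_id; undefined scores (images without ground truth) are NaN and
    listed in ``undefined_images``. ``scores`` keeps the full PerImageScore
    objects keyed by (image_id, variant_id).
    """

    values: pd.DataFrame
    scores: dict[tuple[int, int], PerImageScore] = field(default_factory=dict)
    undefined_images: list[int] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[int]:
        return list(self.values.columns)

    def defined(self) -> pd.DataFrame:
        return self.values.dropna(how="any")


def score_matrix(det_sets: list[DetectionSet], gts: GroundTruthSet,
                 interpolation: str = "coco101") -> ScoreMatrix:
    """Score every (image, variant) pair into a matrix.

    ``det_sets`` must have unique variant ids. An image absent from a
    variant's results simply has zero detections there (valid; scores 0 when
    it has ground truth).
    """
    if not det_sets:
        raise ValueError("score_matrix requires at least one detection set")
    variant_ids = [ds.variant_id for ds in det_sets]
    if len(set(variant_ids)) != len(variant_ids):
        raise ValueError(f"duplicate variant ids in detection sets: {variant_ids}")
    image_ids = gts.image_ids
    if not image_ids:
        raise ValueError("ground truth contains no images")
    data = {}
    scores: dict[tuple[int, int], PerImageScore] = {}
    undefined: set[int] = set()
    for ds in det_sets:
        column = []
        for image_id in image_ids:
            score = per_image_map5095(
                ds.for_image(image_id), gts.boxes[image_id], image_id, ds.variant_id, interpolation
            )
            scores[(image_id, ds.variant_id)] = score
            column.append(score.map5095 if score.defined else float("nan"))
            if not score.defined:
                undefined.add(image_id)
        data[ds.variant_id] = column
    values = pd.DataFrame(data, index=pd.Index(image_ids, name="image_id"))
    return ScoreMatrix(values=values, scores=scores, undefined_images=sorted(undefined))
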