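"""COCO-protocol average precision.

Follows the standard COCO evaluation procedure: greedy score-ordered
matching per image/category at ten IoU thresholds (0.50:0.05:0.95),
101-point interpolated precision, area-range breakdown with the 32^2 / 96^2
pixel cutoffs, and a 100-detections-per-image cap.  AP is averaged over
categories that have at least one ground-truth instance.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

__all__ = ["box_iou_xywh", "evaluate_coco", "IOU_THRESHOLDS", "AREA_RANGES"]

IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)
RECALL_THRESHOLDS = np.linspace(0.0, 1.0, 101)
AREA_RANGES = {
    "all": (0.0, float("inf")),
    "small": (0.0, 32.0**2),
    "medium": (32.0**2, 96.0**2),
    "large": (96.0**2, float("inf")),
}
MAX_DETS = 100


def box_iou_xywh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) boxes in (x, y, w, h)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    ax1, ay1 = a[:, 0], a[:, 1]
    ax2, ay2 = a[:, 0] + a[:, 2], a[:, 1] + a[:, 3]
    bx1, by1 = b[:, 0], b[:, 1]
    bx2, by2 = b[:, 0] + b[:, 2], b[:, 1] + b[:, 3]
    ix = np.clip(np.minimum(ax2[:, None], bx2) - np.maximum(ax1[:, None], bx1), 0, None)
    iy = np.clip(np.minimum(ay2[:, None], by2) - np.maximum(ay1[:, None], by1), 0, None)
    inter = ix * iy
    union = (a[:, 2] * a[:, 3])[:, None] + b[:, 2] * b[:, 3] - inter
    return inter / np.maximum(union, 1e-12)


def _evaluate_img(dets, gts, area_rng):
    """Greedy matching for one (image, category) cell.

    Returns (dt_scores, dt_matched[T, D], dt_ignore[T, D], n_gt_unignored).
    """
    lo, hi = area_rng
    gt_ignore = np.array([not (lo <= g["area"] <= hi) for g in gts], dtype=bool)
    # sort gt: unignored first (COCO convention)
    order_g = np.argsort(gt_ignore, kind="mergesort")
    gts = [gts[i] for i in order_g]
    gt_ignore = gt_ignore[order_g]
    scores = np.array([d["score"] for d in dets], dtype=float)
    order_d = np.argsort(-scores, kind="mergesort")[:MAX_DETS]
    dets = [dets[i] for i in order_d]
    scores = scores[order_d]
    T, D, G = len(IOU_THRESHOLDS), len(dets), len(gts)
    dt_match = np.zeros((T, D), dtype=int)  # 1-based gt index, 0 = unmatched
    gt_match = np.zeros((T, G), dtype=int)
    dt_ignore = np.zeros((T, D), dtype=bool)
    if D and G:
        ious = box_iou_xywh([d["bbox"] for d in dets], [g["bbox"] for g in gts])
    else:
        ious = np.zeros((D, G))
    for t, thr in enumerate(IOU_THRESHOLDS):
        for d in range(D):
            best_iou = min(thr, 1 - 1e-10)
            best_g = -1
            for g in range(G):
                if gt_match[t, g]:
                    continue
                # once matched to an unignored gt, never switch to an ignored one
                if best_g > -1 and not gt_ignore[best_g] and gt_ignore[g]:
                    break
                if ious[d, g] < best_iou:
                    continue
                best_iou = ious[d, g]
                best_g = g
            if best_g > -1:
                dt_match[t, d] = best_g + 1
                gt_match[t, best_g] = d + 1
                dt_ignore[t, d] = gt_ignore[best_g]
    # unmatched detections whose area is outside the range are ignored
    dt_area_ignore = np.array(
        [not (lo <= d["bbox"][2] * d["bbox"][3] <= hi) for d in dets], dtype=bool)
    dt_ignore |= (dt_match == 0) & dt_area_ignore[None, :]
    return scores, dt_match > 0, dt_ignore, int((~gt_ignore).sum())


def _accumulate(per_image_results):
    """Average precision over one (category, area-range) slice."""
    scores = np.concatenate([r[0] for r in per_image_results]) if per_image_results else np.zeros(0)
    if scores.size:
        matched = np.concatenate([r[1] for r in per_image_results], axis=1)
        ignored = np.concatenate([r[2] for r in per_image_results], axis=1)
    else:
        matched = np.zeros((len(IOU_THRESHOLDS), 0), dtype=bool)
        ignored = np.zeros((len(IOU_THRESHOLDS), 0), dtype=bool)
    npig = sum(r[3] for r in per_image_results)
    if npig == 0:
        return None
    order = np.argsort(-scores, kind="mergesort")
    matched, ignored = matched[:, order], ignored[:, order]
    ap = np.zeros(len(IOU_THRESHOLDS))
    for t in range(len(IOU_THRESHOLDS)):
        keep = ~ignored[t]
        tp = np.cumsum(matched[t, keep])
        fp = np.cumsum(~matched[t, keep])
        recall = tp / npig
        precision = tp / np.maximum(tp + fp, 1e-12)
        # monotone envelope, then 101-point interpolation
        for i in range(len(precision) - 1, 0, -1):
            precision[i - 1] = max(precision[i - 1], precision[i])
        idx = np.searchsorted(recall, RECALL_THRESHOLDS, side="left")
        q = np.zeros(len(RECALL_THRESHOLDS))
        valid = idx < len(precision)
        q[valid] = precision[idx[valid]]
        ap[t] = q.mean()
    return ap


def evaluate_coco(detections: list[dict], ground_truth: dict) -> dict:
    """COCO-protocol AP family.

    detections: list of {"image_id", "category_id", "bbox" (xywh), "score"}.
    ground_truth: COCO-style dict with "images", "annotations", "categories".
    Returns {"AP", "AP50", "AP75", "APs", "APm", "APl"} (fractions in [0,1];
    -1 where a breakdown has no ground truth).
    """
    img_ids = {im["id"] for im in ground_truth["images"]}
    cat_ids = sorted({c["id"] for c in ground_truth["categories"]})
    for d in detections:
        if d["image_id"] not in img_ids:
            raise DataError(f"detection references unknown image id {d['image_id']}")
        if d["category_id"] not in cat_ids:
            raise DataError(f"detection references unknown category id {d['category_id']}")
    gt_by = {(i, c): [] for i in img_ids for c in cat_ids}
    for ann in ground_truth["annotations"]:
        key = (ann["image_id"], ann["category_id"])
        if key not in gt_by:
            raise DataError(f"annotation {ann.get('id')} has unknown image/category id")
        gt_by[key].append(ann)
    dt_by = {(i, c): [] for i in img_ids for c in cat_ids}
    for d in detections:
        dt_by[(d["image_id"], d["category_id"])].append(d)

    ap_slices = {name: [] for name in AREA_RANGES}
    for c in cat_ids:
        for name, rng in AREA_RANGES.items():
            results = [_evaluate_img(dt_by[(i, c)], gt_by[(i, c)], rng)
                       for i in img_ids]
            ap = _accumulate(results)
            if ap is not None:
                ap_slices[name].append(ap)

    def _mean(name, t_idx=None):
        slices = ap_slices[name]
        if not slices:
            return -1.0
        arr = np.stack(slices)  # (n_cats, T)
        return float(arr.mean() if t_idx is None else arr[:, t_idx].mean())

    return {
        "AP": _mean("all"),
        "AP50": _mean("all", 0),
        "AP75": _mean("all", 5),
        "APs": _mean("small"),
        "APm": _mean("medium"),
        "APl": _mean("large"),
    }
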