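"""COCO-protocol AP against a brute-force precision-recall oracle.

The oracle re-implements the protocol with literal loops: score-sorted
greedy matching per image, explicit cumulative PR curve, monotone envelope,
101-point interpolation — no shared code with the package evaluator.
"""

import numpy as np
import pytest

from reefblocks.cocoeval import IOU_THRESHOLDS, box_iou_xywh, evaluate_coco
from reefblocks.errors import DataError


def _iou(a, b):
    ax1, ay1, ax2, ay2 = a[0], a[1], a[0] + a[2], a[1] + a[3]
    bx1, by1, bx2, by2 = b[0], b[1], b[0] + b[2], b[1] + b[3]
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    return inter / (a[2] * a[3] + b[2] * b[3] - inter)


def brute_force_ap(dets, gts, img_ids, thr):
    """Single-category AP at one IoU threshold by explicit enumeration."""
    records = []  # (score, is_tp)
    n_gt = len(gts)
    for img in img_ids:
        img_dets = sorted([d for d in dets if d["image_id"] == img],
                          key=lambda d: -d["score"])
        img_gts = [g for g in gts if g["image_id"] == img]
        taken = [False] * len(img_gts)
        for d in img_dets:
            best, best_iou = -1, thr
            for gi, g in enumerate(img_gts):
                if taken[gi]:
                    continue
                iou = _iou(d["bbox"], g["bbox"])
                if iou >= best_iou:
                    best, best_iou = gi, iou
            if best >= 0:
                taken[best] = True
                records.append((d["score"], True))
            else:
                records.append((d["score"], False))
    if n_gt == 0:
        return None
    records.sort(key=lambda r: -r[0])
    tp = fp = 0
    pr = []
    for _, is_tp in records:
        tp += is_tp
        fp += not is_tp
        pr.append((tp / n_gt, tp / (tp + fp)))
    # monotone precision envelope
    for i in range(len(pr) - 2, -1, -1):
        pr[i] = (pr[i][0], max(pr[i][1], pr[i + 1][1]))
    total = 0.0
    for r in np.linspace(0, 1, 101):
        p = 0.0
        for rec, prec in pr:
            if rec >= r:
                p = prec
                break
        total += p
    return total / 101


def make_gt(boxes_by_image, categories=(0,)):
    images = [{"id": i, "width": 640, "height": 640}
              for i in sorted(boxes_by_image)]
    anns = []
    k = 1
    for i in sorted(boxes_by_image):
        for (cat, box) in boxes_by_image[i]:
            anns.append({"id": k, "image_id": i, "category_id": cat,
                         "bbox": list(box), "area": box[2] * box[3],
                         "iscrowd": 0})
            k += 1
    return {"images": images, "annotations": anns,
            "categories": [{"id": c, "name": str(c)} for c in categories]}


class TestEvaluateCoco:
    def test_perfect_detections_give_ap_one(self):
        gt = make_gt({1: [(0, (10, 10, 50, 40))], 2: [(0, (100, 100, 80, 80))]})
        dets = [{"image_id": i, "category_id": 0, "bbox": a["bbox"], "score": 1.0}
                for i, a in [(1, gt["annotations"][0]), (2, gt["annotations"][1])]]
        res = evaluate_coco(dets, gt)
        assert res["AP"] == pytest.approx(1.0)
        assert res["AP50"] == pytest.approx(1.0)

    def test_no_detections_give_ap_zero(self):
        gt = make_gt({1: [(0, (10, 10, 50, 40))]})
        assert evaluate_coco([], gt)["AP"] == 0.0

    def test_hand_built_false_positive_case_matches_enumeration(self):
        """Three gt boxes, two hits and one high-scoring false positive."""
        gt = make_gt({1: [(0, (0, 0, 50, 50)), (0, (100, 100, 50, 50))],
                      2: [(0, (200, 200, 60, 60))]})
        dets = [
            {"image_id": 1, "category_id": 0, "bbox": (0, 0, 50, 50), "score": 0.9},
            {"image_id": 1, "category_id": 0, "bbox": (400, 400, 40, 40), "score": 0.95},
            {"image_id": 2, "category_id": 0, "bbox": (200, 200, 60, 60), "score": 0.8},
        ]
        res = evaluate_coco(dets, gt)
        expected = brute_force_ap(dets, gt["annotations"], [1, 2], 0.5)
        assert res["AP50"] == pytest.approx(expected, abs=1e-12)

    def test_randomized_small_cases_match_oracle_at_every_threshold(self, rng):
        for trial in range(5):
            n_imgs = int(rng.integers(2, 8))
            boxes_by_image = {}
            for i in range(1, n_imgs + 1):
                n = int(rng.integers(0, 5))
                boxes_by_image[i] = [
                    (0, tuple(np.round([*rng.uniform(0, 400, 2),
                                        *rng.uniform(20, 200, 2)], 1)))
                    for _ in range(n)]
            gt = make_gt(boxes_by_image)
            dets = []
            for i in range(1, n_imgs + 1):
                for (_, box) in boxes_by_image[i]:
                    if rng.random() < 0.8:  # jittered true positive
                        jit = rng.normal(0, 8, 4)
                        dets.append({"image_id": i, "category_id": 0,
                                     "bbox": tuple(np.array(box) + jit),
                                     "score": float(rng.random())})
                if rng.random() < 0.5:  # random false positive
                    dets.append({"image_id": i, "category_id": 0,
                                 "bbox": tuple([*rng.uniform(0, 500, 2),
                                                *rng.uniform(10, 100, 2)]),
                                 "score": float(rng.random())})
            res = evaluate_coco(dets, gt)
            oracle = np.mean([brute_force_ap(dets, gt["annotations"],
                                             list(boxes_by_image), thr)
                              for thr in IOU_THRESHOLDS])
            assert res["AP"] == pytest.approx(float(oracle), abs=1e-10)

    def test_unknown_image_id_rejected(self):
        gt = make_gt({1: [(0, (0, 0, 10, 10))]})
        with pytest.raises(DataError):
            evaluate_coco([{"image_id": 99, "category_id": 0,
                            "bbox": (0, 0, 10, 10), "score": 1.0}], gt)

    def test_area_breakdown_uses_coco_cutoffs(self):
        """A 20x20 gt counts toward APs, a 200x200 toward APl."""
        gt = make_gt({1: [(0, (0, 0, 20, 20)), (0, (100, 100, 200, 200))]})
        dets = [{"image_id": 1, "category_id": 0, "bbox": (0, 0, 20, 20),
                 "score": 0.9},
                {"image_id": 1, "category_id": 0, "bbox": (100, 100, 200, 200),
                 "score": 0.8}]
        res = evaluate_coco(dets, gt)
        assert res["APs"] == pytest.approx(1.0)
        assert res["APl"] == pytest.approx(1.0)
        assert res["APm"] == -1.0  # no medium ground truth

    def test_pairwise_iou_matches_scalar(self, rng):
        a = rng.uniform(0, 100, (5, 4)) + [[0, 0, 10, 10]]
        b = rng.uniform(0, 100, (3, 4)) + [[0, 0, 10, 10]]
        got = box_iou_xywh(a, b)
        for i in range(5):
            for j in range(3):
                assert got[i, j] == pytest.approx(_iou(a[i], b[j]), abs=1e-12)
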