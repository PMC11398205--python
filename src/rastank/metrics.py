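"""Single-class detector evaluation: IoU, greedy matching, AP at IoU 0.5, F1.

Boxes are (x, y, w, h) in pixels with half-open pixel-area convention
(area = w * h). Matching is the standard greedy protocol: detections in
descending confidence order each claim the unmatched ground-truth box of
highest IoU >= threshold; a ground truth is matched at most once. AP is the
area under the all-points precision envelope of the pooled ranking; F1 is
reported at the confidence threshold that maximises it over the ranking
sweep (exposed alongside the full curve, since operating points differ
between tools). Equal-confidence ties keep input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, UndefinedMetricError

Box = tuple[float, float, float, float]


@dataclass
class ImageDetections:
    """Scored predictions and ground truth boxes for one image."""

    detections: list[tuple[Box, float]] = field(default_factory=list)
    ground_truths: list[Box] = field(default_factory=list)

    def __post_init__(self):
        for _, conf in self.detections:
            if not (0.0 <= conf <= 1.0):
                raise InvalidArgumentError(f"confidence {conf} outside [0, 1]")


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise InvalidArgumentError("boxes must have positive width and height")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def match_detections(
    detections: list[tuple[Box, float]],
    ground_truths: list[Box],
    iou_thr: float = 0.5,
) -> tuple[list[bool], list[bool]]:
    """Greedy confidence-ordered matching for one image.

    ``detections`` must already be sorted by descending confidence. Returns
    (per-detection TP flags in the given order, per-ground-truth matched
    flags). Ties in IoU break toward the lower ground-truth index.
    """
    gt_matched = [False] * len(ground_truths)
    tp = []
    for box, _conf in detections:
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(ground_truths):
            if gt_matched[j]:
                continue
            v = iou(box, gt)
            if v > best_iou:  # strict: earlier (lower) index wins ties
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thr:
            gt_matched[best_j] = True
            tp.append(True)
        else:
            tp.append(False)
    return tp, gt_matched


def _pooled_ranking(image_sets: list[ImageDetections], iou_thr: float):
    """Pool per-image matches into one confidence-ranked TP/FP sequence."""
    confs: list[float] = []
    flags: list[bool] = []
    n_gt = 0
    for s in image_sets:
        n_gt += len(s.ground_truths)
        order = np.argsort([-c for _, c in s.detections], kind="stable")
        dets_sorted = [s.detections[i] for i in order]
        tp, _ = match_detections(dets_sorted, s.ground_truths, iou_thr)
        confs.extend(c for _, c in dets_sorted)
        flags.extend(tp)
    order = np.argsort([-c for c in confs], kind="stable")
    return [flags[i] for i in order], [confs[i] for i in order], n_gt


def precision_recall_curve(
    image_sets: list[ImageDetections], iou_thr: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(precision, recall, confidence) arrays along the pooled ranking."""
    flags, confs, n_gt = _pooled_ranking(image_sets, iou_thr)
    if n_gt == 0:
        raise UndefinedMetricError("precision-recall undefined with zero ground-truth boxes")
    tp_cum = np.cumsum(flags) if flags else np.array([])
    k = np.arange(1, len(flags) + 1)
    precision = tp_cum / k if len(flags) else np.array([])
    recall = tp_cum / n_gt if len(flags) else np.array([])
    return precision, recall, np.asarray(confs)


def average_precision(image_sets: list[ImageDetections], iou_thr: float = 0.5) -> float:
    """Area under the all-points precision envelope at the given IoU threshold."""
    precision, recall, _ = precision_recall_curve(image_sets, iou_thr)
    if len(precision) == 0:
        return 0.0
    # prepend recall 0; envelope = running max of precision from the right
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[1.0], precision])
    env = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * env[1:]))


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise InvalidArgumentError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def f1_sweep(image_sets: list[ImageDetections], iou_thr: float = 0.5):
    """F1 at every confidence cutoff along the ranking; returns (best_f1, table).

    The table rows are (confidence, precision, recall, f1) at each prefix of
    the pooled ranking. Best F1 is the maximum over the sweep (0 if there are
    no detections).
    """
    precision, recall, confs = precision_recall_curve(image_sets, iou_thr)
    rows = [
        (float(c), float(p), float(r), f1(float(p), float(r)))
        for c, p, r in zip(confs, precision, recall)
    ]
    best = max((row[3] for row in rows), default=0.0)
    return best, rows


def evaluate(image_sets: list[ImageDetections], iou_thr: float = 0.5) -> dict:
    """Convenience summary: AP, max-F1 and its operating point."""
    ap = average_precision(image_sets, iou_thr)
    best_f1, rows = f1_sweep(image_sets, iou_thr)
    at = next((row for row in rows if row[3] == best_f1), None)
    return {
        "ap": ap,
        "max_f1": best_f1,
        "f1_confidence": at[0] if at else None,
        "precision_at_max_f1": at[1] if at else None,
        "recall_at_max_f1": at[2] if at else None,
        "iou_threshold": iou_thr,
    }


def detections_from_coco(gt_doc: dict, det_entries: list[dict], iou_thr: float = 0.5
                         ) -> list[ImageDetections]:
    """Pair a COCO ground-truth document with a detection-results list.

    ``det_entries`` follow the COCO results convention: dicts with image_id,
    bbox [x, y, w, h], and score.
    """
    by_image: dict[int, ImageDetections] = {
        im["id"]: ImageDetections() for im in gt_doc["images"]
    }
    for ann in gt_doc["annotations"]:
        by_image[ann["image_id"]].ground_truths.append(tuple(ann["bbox"]))
    for d in det_entries:
        img = d["image_id"]
        if img not in by_image:
            raise InvalidArgumentError(f"detection references unknown image id {img}")
        by_image[img].detections.append((tuple(d["bbox"]), float(d["score"])))
    return [by_image[im["id"]] for im in gt_doc["images"]]
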