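"""Evaluation metrics: detection PR/AP/mAP, accuracy, CLEAR-MOT, counting.

Detection metrics use greedy confidence-ordered matching at an IOU
threshold and all-points interpolation of the precision-recall curve.
Tracking metrics follow the CLEAR protocol: per-frame matching with
persistence (last frame's correspondences are kept while still valid, the
rest matched optimally), accumulating misses m_t, false positives fp_t and
mismatches mme_t against the ground-truth count g_t:

    MOTA = 1 - sum_t (m_t + fp_t + mme_t) / sum_t g_t
    MOTP = sum_{i,t} d_t^i / sum_t c_t

where d is the matched-pair distance (default 1 - IOU; a pixel
center-distance mode is available) and c_t the number of matches.
Counting metrics are the mean absolute error and coefficient of
determination of predicted vs true per-video counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import Box, iou

__all__ = ["DetectionPR", "detection_pr", "mean_ap", "accuracy",
           "ClearMotResult", "clearmot", "counting_eval"]


# ---------------------------------------------------------------- detection

@dataclass(frozen=True)
class DetectionPR:
    precision: float
    recall: float
    ap: float
    tp: int
    fp: int
    fn: int


def _match_frame(preds: list[tuple[Box, float]], gts: list[Box],
                 iou_threshold: float) -> list[bool]:
    """Greedy confidence-ordered matching; returns per-prediction TP flags
    in the original prediction order."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
    used = [False] * len(gts)
    flags = [False] * len(preds)
    for i in order:
        box = preds[i][0]
        best, best_iou = -1, iou_threshold
        for j, gt in enumerate(gts):
            if used[j]:
                continue
            o = iou(box, gt)
            if o >= best_iou:
                best, best_iou = j, o
        if best >= 0:
            used[best] = True
            flags[i] = True
    return flags


def detection_pr(predictions: dict[int, list[tuple[Box, float]]],
                 ground_truth: dict[int, list[Box]],
                 iou_threshold: float = 0.5) -> DetectionPR:
    """Precision, recall and average precision of per-frame detections.

    ``predictions`` maps frame -> [(box, confidence)], ``ground_truth``
    maps frame -> [box].  AP integrates the precision envelope over recall
    (all-points interpolation).
    """
    n_gt = sum(len(v) for v in ground_truth.values())
    scored: list[tuple[float, bool]] = []
    for frame, preds in predictions.items():
        flags = _match_frame(preds, ground_truth.get(frame, []), iou_threshold)
        for (box, conf), is_tp in zip(preds, flags):
            scored.append((conf, is_tp))
    if not scored:
        return DetectionPR(0.0, 0.0, 0.0, 0, 0, n_gt)
    scored.sort(key=lambda t: -t[0])
    tps = np.cumsum([t[1] for t in scored])
    fps = np.cumsum([not t[1] for t in scored])
    recalls = tps / n_gt if n_gt else np.zeros_like(tps, dtype=float)
    precisions = tps / (tps + fps)
    # all-points AP: integrate the precision envelope over recall
    mrec = np.concatenate(([0.0], recalls, [recalls[-1]]))
    mpre = np.concatenate(([1.0], precisions, [0.0]))
    for i in range(mpre.size - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    ap = float(np.sum(np.diff(mrec) * mpre[1:]))
    tp, fp = int(tps[-1]), int(fps[-1])
    return DetectionPR(precision=float(precisions[-1]), recall=float(recalls[-1]),
                       ap=ap, tp=tp, fp=fp, fn=n_gt - tp)


def mean_ap(predictions, ground_truth,
            thresholds=(0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95),
            ) -> float:
    """mAP over IOU thresholds (single class: the mean over classes of the
    per-class AP reduces to the AP)."""
    return float(np.mean([detection_pr(predictions, ground_truth, t).ap
                          for t in thresholds]))


# ------------------------------------------------------------ classification

def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("accuracy undefined for zero total")
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    return (tp + tn) / total


# ---------------------------------------------------------------- CLEAR-MOT

@dataclass
class ClearMotResult:
    mota: float
    motp: float
    misses: int
    false_positives: int
    mismatches: int
    gt_total: int
    matches_total: int
    distance_total: float
    per_frame: list[dict[str, int]] = field(default_factory=list)


def clearmot(ground_truth: dict[int, list[tuple[int, Box]]],
             hypotheses: dict[int, list[tuple[int, Box]]],
             iou_threshold: float = 0.5,
             distance: str = "iou") -> ClearMotResult:
    """CLEAR-MOT accounting of hypothesis tracks against ground truth.

    Inputs map frame -> [(id, box)].  ``distance`` selects the matched-pair
    distance d: "iou" gives d = 1 - IOU (bounded [0,1]); "pixel" gives the
    center distance in pixels.
    """
    if distance not in ("iou", "pixel"):
        raise ValueError("distance must be 'iou' or 'pixel'")
    frames = sorted(set(ground_truth) | set(hypotheses))
    last_match: dict[int, int] = {}   # gt id -> hyp id (persistent correspondence)
    misses = false_pos = mismatches = gt_total = matches_total = 0
    dist_total = 0.0
    per_frame = []

    for f in frames:
        gts = ground_truth.get(f, [])
        hyps = hypotheses.get(f, [])
        gt_total += len(gts)
        gt_ids = [g[0] for g in gts]
        hyp_ids = [h[0] for h in hyps]
        matched_g: dict[int, int] = {}  # gt index -> hyp index

        # keep still-valid correspondences from previous frames
        for gi, (gid, gbox) in enumerate(gts):
            if gid in last_match and last_match[gid] in hyp_ids:
                hi = hyp_ids.index(last_match[gid])
                if hi not in matched_g.values() and iou(gbox, hyps[hi][1]) >= iou_threshold:
                    matched_g[gi] = hi

        # optimally match the rest
        free_g = [i for i in range(len(gts)) if i not in matched_g]
        free_h = [i for i in range(len(hyps)) if i not in matched_g.values()]
        if free_g and free_h:
            cost = np.full((len(free_g), len(free_h)), 1e5)
            for r, gi in enumerate(free_g):
                for c, hi in enumerate(free_h):
                    o = iou(gts[gi][1], hyps[hi][1])
                    if o >= iou_threshold:
                        cost[r, c] = 1.0 - o
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < 1e5:
                    matched_g[free_g[r]] = free_h[c]

        frame_mme = 0
        for gi, hi in matched_g.items():
            gid, gbox = gts[gi]
            hid, hbox = hyps[hi]
            if gid in last_match and last_match[gid] != hid:
                frame_mme += 1
            last_match[gid] = hid
            if distance == "iou":
                dist_total += 1.0 - iou(gbox, hbox)
            else:
                dist_total += float(np.hypot(gbox.cx - hbox.cx, gbox.cy - hbox.cy))
        frame_m = len(gts) - len(matched_g)
        frame_fp = len(hyps) - len(matched_g)
        misses += frame_m
        false_pos += frame_fp
        mismatches += frame_mme
        matches_total += len(matched_g)
        per_frame.append({"frame": f, "m": frame_m, "fp": frame_fp,
                          "mme": frame_mme, "g": len(gts), "c": len(matched_g)})

    mota = 1.0 - (misses + false_pos + mismatches) / gt_total if gt_total else float("nan")
    motp = dist_total / matches_total if matches_total else float("nan")
    return ClearMotResult(mota=mota, motp=motp, misses=misses,
                          false_positives=false_pos, mismatches=mismatches,
                          gt_total=gt_total, matches_total=matches_total,
                          distance_total=dist_total, per_frame=per_frame)


# ----------------------------------------------------------------- counting

def counting_eval(true_counts, predicted_counts) -> tuple[float, float]:
    """MAE and R² of predicted vs true counts.

    R² is NaN when the true counts have zero variance (undefined).
    """
    y = np.asarray(true_counts, dtype=float)
    yhat = np.asarray(predicted_counts, dtype=float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("count vectors must be equal-length and non-empty")
    mae = float(np.mean(np.abs(yhat - y)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return mae, float("nan")
    ss_res = float(np.sum((y - yhat) ** 2))
    return mae, 1.0 - ss_res / ss_tot
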