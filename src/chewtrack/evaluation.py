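"""Evaluation metrics: OKS / AP / mAP for keypoints, error rate for counts.

Keypoint accuracy is scored with object keypoint similarity (OKS), the
Gaussian-kernel similarity used throughout pose estimation:

    OKS = sum_i exp(-d_i^2 / (2 * s * sigma_i^2)) * [v_i > 0]
          ------------------------------------------------------
                        sum_i [v_i > 0]

where ``d_i`` is the pixel distance between predicted and ground-truth
keypoint ``i``, ``s`` the object's bounding-box area, ``sigma_i`` the
per-keypoint spread constant, and ``v_i`` the visibility flag.  Average
precision at threshold ``T`` is the fraction of instances whose OKS
exceeds ``T``; mAP averages AP over thresholds (0.50:0.05:0.95) or
categories.

Chew-count accuracy is a relative error: |assessed - measured| over a
reference count, in percent, summarised over videos by the mean and the
population standard deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .trajectory import TrajectoryError

__all__ = [
    "OksParams",
    "KeypointEvalResult",
    "oks",
    "average_precision",
    "mean_ap",
    "precision_recall",
    "relative_error",
    "error_summary",
    "count_report",
    "evaluate_keypoints",
    "load_coco_keypoints",
    "OKS_THRESHOLDS",
]

OKS_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))

# COCO's face-keypoint spread constants are ~0.025-0.035; nose/mouth on a
# bovine face are comparably tight landmarks.
DEFAULT_SIGMA = 0.025


@dataclass(frozen=True)
class OksParams:
    """Per-instance OKS parameters.

    ``bbox_area`` is the target bounding-box area in px^2; ``sigmas`` one
    spread constant per keypoint; ``visibility`` the per-keypoint flags.
    ``strict_as_printed`` squares the area in the kernel denominator
    (2*area^2*sigma^2) instead of the conventional 2*area*sigma^2.
    """

    bbox_area: float
    sigmas: tuple[float, ...] = (DEFAULT_SIGMA, DEFAULT_SIGMA)
    visibility: Optional[tuple[int, ...]] = None
    strict_as_printed: bool = False

    def validate(self) -> None:
        if self.bbox_area <= 0:
            raise TrajectoryError("bbox_area must be positive")
        if any(s <= 0 for s in self.sigmas):
            raise TrajectoryError("sigmas must be positive")


@dataclass
class KeypointEvalResult:
    oks_values: np.ndarray
    ap_by_threshold: dict[float, float]
    map_50: float
    map_50_95: float
    precision: float
    recall: float
    tp: int = 0
    fp: int = 0
    fn: int = 0


def oks(
    pred: Sequence[Sequence[float]],
    gt: Sequence[Sequence[float]],
    params: OksParams,
) -> float:
    """Object keypoint similarity between aligned keypoint sets.

    ``pred`` and ``gt`` are sequences of (x, y) pairs aligned by keypoint
    identity.  Visibility comes from ``params.visibility`` (default: all
    visible).  At least one ground-truth keypoint must be visible.
    """
    params.validate()
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape or pred.ndim != 2 or pred.shape[1] != 2:
        raise TrajectoryError("pred and gt must be aligned (n, 2) keypoint arrays")
    n = pred.shape[0]
    sigmas = np.asarray(params.sigmas, dtype=float)
    if len(sigmas) != n:
        raise TrajectoryError(f"expected {n} sigmas, got {len(sigmas)}")
    vis = (np.asarray(params.visibility, dtype=float) > 0
           if params.visibility is not None else np.ones(n, dtype=bool))
    if not vis.any():
        raise TrajectoryError("OKS undefined with no visible keypoints")

    d2 = np.sum((pred - gt) ** 2, axis=1)
    scale = params.bbox_area ** 2 if params.strict_as_printed else params.bbox_area
    with np.errstate(over="ignore"):
        k = np.exp(-d2 / (2.0 * scale * sigmas ** 2))
    return float(np.sum(k[vis]) / np.sum(vis))


def average_precision(
    oks_values: Sequence[float],
    T: float,
    mode: Literal["indicator", "as_printed"] = "indicator",
) -> float:
    """AP at OKS threshold ``T``.

    ``indicator`` counts the fraction of instances with OKS > T;
    ``as_printed`` averages the OKS values themselves, zeroing those at or
    below T (the literal piecewise form).
    """
    vals = np.asarray(oks_values, dtype=float)
    if len(vals) == 0:
        raise TrajectoryError("average_precision needs at least one OKS value")
    if np.any((vals < 0) | (vals > 1)) or not 0 <= T <= 1:
        raise TrajectoryError("OKS values and T must lie in [0, 1]")
    if mode == "indicator":
        return float(np.mean(vals > T))
    if mode == "as_printed":
        return float(np.mean(np.where(vals > T, vals, 0.0)))
    raise TrajectoryError(f"unknown AP mode {mode!r}")


def mean_ap(ap_values: Sequence[float]) -> float:
    """Arithmetic mean of AP values (over categories or thresholds)."""
    vals = np.asarray(ap_values, dtype=float)
    if len(vals) == 0:
        raise TrajectoryError("mean_ap needs at least one AP value")
    return float(np.mean(vals))


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Standard precision TP/(TP+FP) and recall TP/(TP+FN).

    A zero denominator yields NaN rather than an exception.
    """
    if min(tp, fp, fn) < 0:
        raise TrajectoryError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return precision, recall


def relative_error(
    assessed: float,
    measured: float,
    denominator: Literal["assessed", "measured"] = "assessed",
) -> float:
    """Chew-count error rate in percent: 100*|assessed - measured|/reference.

    ``assessed`` is the pipeline's count, ``measured`` the manual tally.
    The default reference is the assessed count; ``"measured"`` divides by
    the manual tally instead.
    """
    ref = assessed if denominator == "assessed" else measured
    if denominator not in ("assessed", "measured"):
        raise TrajectoryError(f"unknown denominator {denominator!r}")
    if ref <= 0:
        raise TrajectoryError("reference count must be positive")
    return 100.0 * abs(assessed - measured) / ref


def error_summary(errors: Sequence[float]) -> tuple[float, float]:
    """Mean and population standard deviation (divisor n) of error percents."""
    vals = np.asarray(errors, dtype=float)
    if len(vals) == 0:
        raise TrajectoryError("error_summary needs at least one value")
    return float(np.mean(vals)), float(np.std(vals, ddof=0))


def count_report(
    counts: pd.DataFrame,
    denominator: Literal["assessed", "measured"] = "assessed",
) -> pd.DataFrame:
    """Per-video relative errors plus mean / population-std footer rows.

    ``counts`` needs ``video_id``, ``assessed`` and ``measured`` columns
    (``duration_s`` is carried through when present).  Rounding to two
    decimals is applied at reporting time only.
    """
    if len(counts) == 0:
        raise TrajectoryError("count table is empty")
    errors = [
        relative_error(a, m, denominator)
        for a, m in zip(counts["assessed"], counts["measured"])
    ]
    mean, std = error_summary(errors)
    body = counts.copy()
    body["relative_error_pct"] = np.round(errors, 2)
    footer = pd.DataFrame(
        {
            "video_id": ["mean", "std"],
            "relative_error_pct": [round(mean, 2), round(std, 2)],
        }
    )
    return pd.concat([body, footer], ignore_index=True)


# ---------------------------------------------------------------------------
# COCO-style keypoint evaluation


def load_coco_keypoints(path: Union[str, Path]) -> dict[int, list[dict]]:
    """Load a COCO-style keypoint JSON into {image_id: [instances]}.

    Each instance dict carries ``keypoints`` as an (n, 3) array of
    (x, y, v) triples and ``bbox_area`` (from ``area`` or the bbox).
    """
    with open(path) as fh:
        doc = json.load(fh)
    anns = doc["annotations"] if isinstance(doc, dict) else doc
    by_image: dict[int, list[dict]] = {}
    for ann in anns:
        kps = np.asarray(ann["keypoints"], dtype=float).reshape(-1, 3)
        if "area" in ann and ann["area"]:
            area = float(ann["area"])
        elif "bbox" in ann:
            _, _, w, h = ann["bbox"]
            area = float(w) * float(h)
        else:
            raise TrajectoryError("annotation needs 'area' or 'bbox'")
        by_image.setdefault(int(ann["image_id"]), []).append(
            {"keypoints": kps, "bbox_area": area,
             "score": float(ann.get("score", 1.0))}
        )
    return by_image


def _instance_oks(pred: dict, gt: dict, sigmas: tuple[float, ...],
                  strict_as_printed: bool) -> float:
    params = OksParams(
        bbox_area=gt["bbox_area"],
        sigmas=sigmas,
        visibility=tuple(int(v) for v in gt["keypoints"][:, 2]),
        strict_as_printed=strict_as_printed,
    )
    return oks(pred["keypoints"][:, :2], gt["keypoints"][:, :2], params)


def evaluate_keypoints(
    gt_by_image: dict[int, list[dict]],
    pred_by_image: dict[int, list[dict]],
    sigmas: tuple[float, ...] = (DEFAULT_SIGMA, DEFAULT_SIGMA),
    match_threshold: float = 0.5,
    ap_mode: Literal["indicator", "as_printed"] = "indicator",
    strict_as_printed: bool = False,
) -> KeypointEvalResult:
    """Match predictions to ground truth per image and score them.

    Matching is greedy by descending OKS within each image: each
    prediction may claim at most one ground truth.  A prediction is a true
    positive when its matched OKS exceeds ``match_threshold``, otherwise a
    false positive; unmatched ground truths are false negatives.
    Unmatched predictions contribute OKS 0 to the AP pool.
    """
    matched_oks: list[float] = []
    tp = fp = fn = 0
    for image_id, gts in gt_by_image.items():
        preds = pred_by_image.get(image_id, [])
        pairs = []
        for pi, p in enumerate(preds):
            for gi, g in enumerate(gts):
                visible = np.any(g["keypoints"][:, 2] > 0)
                score = (_instance_oks(p, g, sigmas, strict_as_printed)
                         if visible else 0.0)
                pairs.append((score, pi, gi))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_p: set[int] = set()
        used_g: set[int] = set()
        for score, pi, gi in pairs:
            if pi in used_p or gi in used_g:
                continue
            used_p.add(pi)
            used_g.add(gi)
            matched_oks.append(score)
            if score > match_threshold:
                tp += 1
            else:
                fp += 1
        fp += len(preds) - len(used_p)
        fn += len(gts) - len(used_g)
        matched_oks.extend([0.0] * (len(preds) - len(used_p)))

    if not matched_oks:
        raise TrajectoryError("no predictions to evaluate")
    oks_arr = np.asarray(matched_oks)
    ap_by_t = {t: average_precision(oks_arr, t, ap_mode) for t in OKS_THRESHOLDS}
    precision, recall = precision_recall(tp, fp, fn)
    return KeypointEvalResult(
        oks_values=oks_arr,
        ap_by_threshold=ap_by_t,
        map_50=ap_by_t[0.5],
        map_50_95=mean_ap(list(ap_by_t.values())),
        precision=precision,
        recall=recall,
        tp=tp, fp=fp, fn=fn,
    )
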