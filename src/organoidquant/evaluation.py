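"""Detection evaluation: per-image ground-truth recovery at 0.7 IoU.

The metric here is the fraction of ground-truth boxes found per image
(a predicted box counts as finding a ground-truth box when their IoU is
at least 0.7; each ground-truth box can be found at most once), averaged
over images. Under the standard detection taxonomy this is a recall —
false positives do not lower it — but it is the metric this tool's
evaluation is defined by, so the conventional VOC/COCO average precision
is deliberately not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .geometry import Box, Detection, greedy_match_boxes

__all__ = [
    "EvaluationReport",
    "per_image_precision",
    "mean_average_precision",
    "write_report_csv",
]

DEFAULT_MATCH_IOU = 0.7


@dataclass
class EvaluationReport:
    per_image: dict[str, float]
    map_value: float
    n_images: int
    n_gt_boxes: int
    match_iou: float


def per_image_precision(
    gt: Sequence[Box],
    pred: Sequence[Detection | Box],
    match_iou: float = DEFAULT_MATCH_IOU,
) -> float:
    """Fraction of ground-truth boxes matched by predictions at ``match_iou``.

    Each ground-truth box matches at most one prediction (duplicates of
    one organoid count once). With two ground-truth boxes and one of
    them found this is 0.5; with both found, 1.0.

    Raises
    ------
    ValueError
        If ``gt`` is empty — the fraction is undefined; such images are
        excluded from the mean by :func:`mean_average_precision`.
    """
    if len(gt) == 0:
        raise ValueError("per-image precision undefined for zero ground-truth boxes")
    pred_boxes = [p.box if isinstance(p, Detection) else p for p in pred]
    matching = greedy_match_boxes(list(gt), pred_boxes, match_iou)
    return matching.n_matched / len(gt)


def mean_average_precision(
    dataset: Sequence[tuple[Sequence[Box], Sequence[Detection | Box]]] | dict,
    match_iou: float = DEFAULT_MATCH_IOU,
) -> EvaluationReport:
    """Mean of per-image precisions over images with >= 1 ground-truth box.

    ``dataset`` is either a sequence of ``(gt_boxes, predictions)``
    pairs or a mapping ``image_id -> (gt_boxes, predictions)``. Images
    with no ground-truth boxes are skipped (their precision is
    undefined); at least one evaluable image is required.
    """
    if isinstance(dataset, dict):
        pairs = list(dataset.items())
    else:
        pairs = [(str(i), pair) for i, pair in enumerate(dataset)]

    per_image: dict[str, float] = {}
    n_gt = 0
    for image_id, (gt, pred) in pairs:
        if len(gt) == 0:
            continue
        n_gt += len(gt)
        per_image[image_id] = per_image_precision(gt, pred, match_iou)
    if not per_image:
        raise ValueError("no evaluable images (every image has zero ground truth)")
    return EvaluationReport(
        per_image=per_image,
        map_value=sum(per_image.values()) / len(per_image),
        n_images=len(per_image),
        n_gt_boxes=n_gt,
        match_iou=match_iou,
    )


def write_report_csv(report: EvaluationReport, path: str | Path) -> None:
    """Write per-image precisions plus a summary row."""
    rows = [
        {"image": k, "precision": round(v, 6)}
        for k, v in sorted(report.per_image.items())
    ]
    rows.append({"image": "__mean__", "precision": round(report.map_value, 6)})
    pd.DataFrame(rows, columns=["image", "precision"]).to_csv(
        path, index=False, lineterminator="\n"
    )
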