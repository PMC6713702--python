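"""Multi-annotator bounding-box consensus.

Crowdsourced annotation workflow: each image patch is boxed by two
workers; if their agreement (IoU-based) falls below 80% the patch is
escalated to a third worker; a consensus box is retained only when at
least 70% of the workers drew it. The platform's exact agreement and
aggregation formulas are not public, so this module implements a
documented, deterministic reading: Dice-style agreement
``2|matches| / (|a| + |b|)`` over a greedy IoU matching, and
fraction-of-workers support for consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import Box, iou

__all__ = [
    "WorkerAnnotationSet",
    "ConsensusResult",
    "pairwise_agreement",
    "needs_escalation",
    "aggregate_consensus",
]

DEFAULT_MATCH_IOU = 0.7
DEFAULT_ESCALATION_THRESHOLD = 0.8
DEFAULT_SUPPORT_THRESHOLD = 0.7


@dataclass(frozen=True)
class WorkerAnnotationSet:
    """All boxes one worker drew on one image patch (may be empty)."""

    worker_id: str
    boxes: tuple[Box, ...]

    def __init__(self, worker_id: str, boxes: Sequence[Box]) -> None:
        object.__setattr__(self, "worker_id", worker_id)
        object.__setattr__(self, "boxes", tuple(boxes))


@dataclass
class ConsensusResult:
    boxes: list[Box] = field(default_factory=list)
    support: list[float] = field(default_factory=list)
    escalated: bool = False


def pairwise_agreement(
    a: WorkerAnnotationSet,
    b: WorkerAnnotationSet,
    match_iou: float = DEFAULT_MATCH_IOU,
) -> float:
    """Dice-style agreement between two workers' box sets.

    Boxes are greedily matched at ``match_iou``; agreement is
    ``2 * matches / (|a| + |b|)``, and 1.0 when both sets are empty
    (two workers who both saw nothing agree perfectly).
    """
    from .geometry import greedy_match_boxes

    na, nb = len(a.boxes), len(b.boxes)
    if na == 0 and nb == 0:
        return 1.0
    matching = greedy_match_boxes(a.boxes, b.boxes, match_iou)
    return 2.0 * matching.n_matched / (na + nb)


def needs_escalation(
    agreement: float, escalation_threshold: float = DEFAULT_ESCALATION_THRESHOLD
) -> bool:
    """True iff agreement is strictly below the threshold (default 80%)."""
    if not 0.0 <= agreement <= 1.0:
        raise ValueError(f"agreement must lie in [0, 1], got {agreement}")
    return agreement < escalation_threshold


def aggregate_consensus(
    workers: Sequence[WorkerAnnotationSet],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    match_iou: float = DEFAULT_MATCH_IOU,
) -> ConsensusResult:
    """Aggregate several workers' boxes into consensus boxes.

    Boxes are clustered across workers by constrained agglomerative
    merging: all cross-worker box pairs with IoU >= ``match_iou`` are
    visited in descending IoU order (ties broken by box coordinates, so
    the result does not depend on worker order), and two clusters merge
    when they share no worker — each worker contributes at most one box
    per cluster. A cluster's support is the fraction of all workers
    contributing to it; clusters at or above ``support_threshold``
    survive, and their consensus box is the coordinate-wise mean of the
    members, rounded to the nearest integer.
    """
    if len(workers) < 2:
        raise ValueError("consensus needs at least 2 workers")

    items: list[tuple[int, Box]] = []  # (worker index, box)
    for wi, wset in enumerate(workers):
        for b in wset.boxes:
            items.append((wi, b))

    # candidate merges: cross-worker pairs above the match threshold
    candidates: list[tuple[float, tuple, tuple, int, int]] = []
    for i, (wi, bi) in enumerate(items):
        for j in range(i + 1, len(items)):
            wj, bj = items[j]
            if wi == wj:
                continue
            v = iou(bi, bj)
            if v >= match_iou:
                lo, hi = sorted([bi.as_tuple(), bj.as_tuple()])
                candidates.append((v, lo, hi, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    parent = list(range(len(items)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cluster_workers: dict[int, set[int]] = {
        i: {wi} for i, (wi, _) in enumerate(items)
    }
    for _, _, _, i, j in candidates:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if cluster_workers[ri] & cluster_workers[rj]:
            continue  # a worker may contribute only one box per cluster
        parent[rj] = ri
        cluster_workers[ri] |= cluster_workers[rj]
        del cluster_workers[rj]

    clusters: dict[int, list[Box]] = {}
    for i, (_, b) in enumerate(items):
        clusters.setdefault(find(i), []).append(b)

    n_workers = len(workers)
    results: list[tuple[Box, float]] = []
    for root, members in clusters.items():
        support = len(cluster_workers[root]) / n_workers
        if support < support_threshold:
            continue
        coords = np.array([m.as_tuple() for m in members], dtype=np.float64)
        mean = np.rint(coords.mean(axis=0)).astype(int)
        results.append((Box(*mean.tolist()), support))
    results.sort(key=lambda t: t[0].as_tuple())

    return ConsensusResult(
        boxes=[b for b, _ in results],
        support=[s for _, s in results],
        escalated=n_workers > 2,
    )
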