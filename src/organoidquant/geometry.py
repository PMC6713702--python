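"""Axis-aligned box arithmetic, IoU, and greedy box matching.

Boxes use 0-based pixel coordinates with the origin at the image top-left
and a half-open convention: a box covers pixel columns ``[xmin, xmax)``
and rows ``[ymin, ymax)``, so its width is exactly ``xmax - xmin`` and
areas are additive. Every other module builds on these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "Box",
    "Detection",
    "BoxMatching",
    "iou",
    "greedy_match_boxes",
    "clip_box",
]


@dataclass(frozen=True, order=True)
class Box:
    """Axis-aligned rectangle in pixel coordinates, half-open.

    Parameters
    ----------
    xmin, ymin : int
        Top-left corner (inclusive), 0-based, origin at the image top-left.
    xmax, ymax : int
        Bottom-right corner (exclusive). Must exceed the min coordinates.
    """

    xmin: int
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self) -> None:
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ValueError(
                f"degenerate box: ({self.xmin},{self.ymin},{self.xmax},{self.ymax}) "
                "requires xmax > xmin and ymax > ymin"
            )

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    @property
    def area(self) -> int:
        return self.width * self.height

    def translate(self, dx: int, dy: int) -> "Box":
        return Box(self.xmin + dx, self.ymin + dy, self.xmax + dx, self.ymax + dy)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    def __iter__(self) -> Iterator[int]:
        return iter(self.as_tuple())


@dataclass(frozen=True)
class Detection:
    """One detected object: a box, a confidence score and a class label."""

    box: Box
    score: float = 1.0
    label: str = "organoid"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class BoxMatching:
    """Result of a one-to-one greedy matching between two box sets.

    ``pairs`` holds ``(index_a, index_b, iou)`` triples; ``unmatched_a``
    and ``unmatched_b`` complete the partition of each input set.
    """

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_a: set[int] = field(default_factory=set)
    unmatched_b: set[int] = field(default_factory=set)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes on half-open pixel areas.

    Returns 0.0 for disjoint boxes and 1.0 iff the boxes are identical.
    """
    iw = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    ih = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union


def greedy_match_boxes(
    set_a: Sequence[Box], set_b: Sequence[Box], iou_threshold: float
) -> BoxMatching:
    """Greedily match two box sets one-to-one in descending IoU order.

    All cross pairs with IoU >= ``iou_threshold`` are considered, highest
    IoU first; each box participates in at most one pair. Ties in IoU are
    broken by (lower A index, lower B index), which makes the result
    deterministic and independent of floating-point sort instability.

    Parameters
    ----------
    set_a, set_b : sequence of Box
    iou_threshold : float
        Minimum IoU for a pair to be matchable, in (0, 1].
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1], got {iou_threshold}")
    candidates: list[tuple[float, int, int]] = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            v = iou(a, b)
            if v >= iou_threshold:
                candidates.append((v, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    matched_a: set[int] = set()
    matched_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for v, i, j in candidates:
        if i in matched_a or j in matched_b:
            continue
        matched_a.add(i)
        matched_b.add(j)
        pairs.append((i, j, v))
    return BoxMatching(
        pairs=pairs,
        unmatched_a=set(range(len(set_a))) - matched_a,
        unmatched_b=set(range(len(set_b))) - matched_b,
    )


def clip_box(b: Box, width: int, height: int) -> Box:
    """Clamp a box into the frame ``[0, width] x [0, height]``.

    Raises
    ------
    ValueError
        If the clamped box is empty (the box lies entirely outside).
    """
    if width <= 0 or height <= 0:
        raise ValueError("frame dimensions must be positive")
    xmin = max(b.xmin, 0)
    ymin = max(b.ymin, 0)
    xmax = min(b.xmax, width)
    ymax = min(b.ymax, height)
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(
            f"box {b.as_tuple()} is empty after clipping to {width}x{height}"
        )
    return Box(xmin, ymin, xmax, ymax)
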