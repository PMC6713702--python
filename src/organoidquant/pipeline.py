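"""End-to-end quantification: tile → detect → filter → aggregate → measure.

One large brightfield image is covered by overlapping square windows
(:mod:`organoidquant.tiling`); a detector backend runs on each window;
detections touching interior window edges are discarded (an organoid cut
by a window edge is seen whole by a neighbouring window, which is why
windows must overlap); survivors are mapped to global coordinates,
de-duplicated across windows by greedy non-maximum suppression, and
measured (:mod:`organoidquant.morphometry`). Batch mode walks a folder
tree and writes a CSV and a labeled overlay next to every image.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import dataset_io, morphometry, tiling
from .detectors import (
    Detector,
    DetectorConfig,
    OracleDetector,
    ReferenceBlobDetector,
    SubprocessAdapterDetector,
    score_threshold_filter,
)
from .geometry import Box, Detection, clip_box, iou
from .morphometry import OrganoidMeasurement
from .tiling import TileGrid

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "BatchSummary",
    "filter_edge_detections",
    "map_to_global",
    "merge_detections",
    "quantify_image",
    "quantify_image_file",
    "batch_quantify",
]

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png"}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs for one run.

    ``overlap`` may be given in pixels (int) or as a fraction of
    ``patch_size`` (float < 1), converted by rounding down. The default
    450-px window with 50% overlap guarantees any organoid smaller than
    the stride is interior to some window.
    """

    patch_size: int = 450
    overlap: float | int = 0.5
    edge_margin: int = 2
    merge_iou_threshold: float = 0.5
    min_score: float = 0.2
    microns_per_pixel: float = 1.0
    detector: str = "reference"
    detector_config: DetectorConfig = field(default_factory=DetectorConfig)
    adapter_command: tuple[str, ...] = ()
    draw_scores: bool = True

    def __post_init__(self) -> None:
        if self.edge_margin < 0:
            raise ValueError("edge_margin must be >= 0")
        if not 0.0 < self.merge_iou_threshold <= 1.0:
            raise ValueError("merge_iou_threshold must lie in (0, 1]")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError("min_score must lie in [0, 1]")

    @property
    def overlap_px(self) -> int:
        if isinstance(self.overlap, float) and self.overlap < 1.0:
            return int(self.overlap * self.patch_size)
        return int(self.overlap)

    def build_detector(self) -> Detector:
        if self.detector == "reference":
            return ReferenceBlobDetector(self.detector_config)
        if self.detector == "adapter":
            if not self.adapter_command:
                raise ValueError("adapter detector requires adapter_command")
            return SubprocessAdapterDetector(self.adapter_command)
        raise ValueError(
            f"unknown detector {self.detector!r} (oracle detectors must be "
            "passed as instances, they need ground truth)"
        )


@dataclass
class BatchSummary:
    processed: int = 0
    failed: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)


def filter_edge_detections(
    dets: Sequence[Detection],
    patch_size: int,
    tile_origin: tuple[int, int],
    grid: TileGrid,
    margin: int,
) -> list[Detection]:
    """Drop detections that come within ``margin`` px of a window side.

    A detector sees organoids cut by its window edge as truncated boxes;
    those are unreliable and the same organoid appears whole in an
    overlapping neighbour, so edge-grazing boxes are discarded. The
    exception: a window side lying on (or beyond, in the padding strip)
    the original image border has no neighbour — boxes at the true image
    border are kept, otherwise perimeter organoids could never be
    reported.
    """
    ox, oy = tile_origin
    check_left = ox > 0
    check_top = oy > 0
    check_right = ox + patch_size < grid.original_width
    check_bottom = oy + patch_size < grid.original_height
    kept: list[Detection] = []
    for d in dets:
        b = d.box
        if check_left and b.xmin < margin:
            continue
        if check_top and b.ymin < margin:
            continue
        if check_right and b.xmax > patch_size - margin:
            continue
        if check_bottom and b.ymax > patch_size - margin:
            continue
        kept.append(d)
    return kept


def map_to_global(
    dets: Sequence[Detection],
    tile_origin: tuple[int, int],
    original_width: int,
    original_height: int,
) -> list[Detection]:
    """Translate tile-local boxes to image coordinates and clip to frame.

    Boxes that end up entirely in the padding strip vanish.
    """
    ox, oy = tile_origin
    out: list[Detection] = []
    for d in dets:
        moved = d.box.translate(ox, oy)
        try:
            clipped = clip_box(moved, original_width, original_height)
        except ValueError:
            continue
        out.append(Detection(box=clipped, score=d.score, label=d.label))
    return out


def merge_detections(
    dets: Sequence[Detection], iou_threshold: float
) -> list[Detection]:
    """Greedy non-maximum suppression across windows.

    Detections are visited by descending score (ties by box
    coordinates); one is kept iff its IoU with every already-kept
    detection is below ``iou_threshold``. Idempotent.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in (0, 1]")
    ordered = sorted(dets, key=lambda d: (-d.score, d.box.as_tuple()))
    kept: list[Detection] = []
    for d in ordered:
        if all(iou(d.box, k.box) < iou_threshold for k in kept):
            kept.append(d)
    return kept


def quantify_image(
    image: np.ndarray,
    config: PipelineConfig,
    detector: Detector | None = None,
) -> tuple[list[Detection], list[OrganoidMeasurement], np.ndarray]:
    """Run the full pipeline on one in-memory image.

    Returns the final detections (sorted by descending score, ties by
    box), their measurements, and the rendered overlay. Zero detections
    is a valid result, not an error.
    """
    if detector is None:
        detector = config.build_detector()
    h, w = image.shape[:2]
    grid = tiling.plan_tile_grid(w, h, config.patch_size, config.overlap_px)
    padded = tiling.pad_image(image, grid)

    global_dets: list[Detection] = []
    for origin, patch in tiling.extract_patches(padded, grid):
        local = detector.detect(patch, origin=origin)
        local = score_threshold_filter(local, config.min_score)
        local = filter_edge_detections(
            local, config.patch_size, origin, grid, config.edge_margin
        )
        global_dets.extend(map_to_global(local, origin, w, h))

    merged = merge_detections(global_dets, config.merge_iou_threshold)
    measurements = [
        morphometry.measure_organoid(d.box, config.microns_per_pixel) for d in merged
    ]
    overlay = morphometry.render_overlay(
        image, merged, draw_scores=config.draw_scores
    )
    return merged, measurements, overlay


def quantify_image_file(
    path: str | Path,
    config: PipelineConfig,
    detector: Detector | None = None,
) -> tuple[list[Detection], list[OrganoidMeasurement]]:
    """Quantify one image file; writes ``<stem>_labels.csv`` and
    ``<stem>_labeled.png`` next to the source image."""
    path = Path(path)
    image = dataset_io.read_image(path)
    dets, measurements, overlay = quantify_image(image, config, detector)
    morphometry.write_measurements_csv(
        measurements, dets, path.with_name(path.stem + "_labels.csv"),
        filename=path.name,
    )
    dataset_io.write_image(path.with_name(path.stem + "_labeled.png"), overlay)
    return dets, measurements


def batch_quantify(
    root: str | Path,
    config: PipelineConfig,
    detector: Detector | None = None,
) -> BatchSummary:
    """Quantify every TIFF/PNG under ``root`` (recursively).

    Per-image failures are logged and skipped so unattended runs over
    large folder trees complete; outputs land beside their sources.
    Overlay images from previous runs (``*_labeled.png``) are ignored.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"root folder does not exist: {root}")
    summary = BatchSummary()
    paths = sorted(
        p
        for p in root.rglob("*")
        if p.suffix.lower() in IMAGE_EXTENSIONS
        and not p.stem.endswith("_labeled")
    )
    for p in paths:
        t0 = time.perf_counter()
        try:
            dets, _ = quantify_image_file(p, config, detector)
        except Exception as exc:  # noqa: BLE001 — error isolation is the contract
            logger.warning("failed on %s: %s", p, exc)
            summary.failed += 1
            summary.failures.append((str(p), str(exc)))
            continue
        dt = time.perf_counter() - t0
        logger.info("%s: %d organoids in %.2f s", p, len(dets), dt)
        summary.processed += 1
    return summary
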