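"""Per-patch detector backends.

The pipeline is detector-agnostic: anything implementing
:meth:`Detector.detect` — take one square patch, return tile-local
:class:`~organoidquant.geometry.Detection` objects deterministically —
can drive it. Three backends are provided:

* :class:`ReferenceBlobDetector` — a classical difference-of-Gaussians
  blob detector with a focus gate, tuned to the synthetic scene
  generator's appearance model. It exists so every downstream stage is
  exercisable end-to-end at desk scale; its parameters describe the
  synthetic fixtures, not real cultures.
* :class:`OracleDetector` — returns known ground-truth boxes clipped to
  the tile; used to verify the tiling/aggregation plumbing in isolation.
* :class:`SubprocessAdapterDetector` — shells out to an external
  detector executable (e.g. a wrapper around a trained neural network),
  exchanging the patch as an 8-bit PNG and detections as annotation-CSV
  rows with a ``score`` column.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .geometry import Box, Detection, clip_box

__all__ = [
    "DetectorConfig",
    "Detector",
    "ReferenceBlobDetector",
    "OracleDetector",
    "SubprocessAdapterDetector",
    "score_threshold_filter",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the reference blob detector.

    smoothing_sigma_fine / smoothing_sigma_coarse : px
        The two Gaussian scales of the band-pass (difference of
        Gaussians) response; fine must be smaller than coarse. Defaults
        bracket the synthetic organoid rim width and body size.
    threshold_mode : {"otsu", "fixed"}
        Binarization of the band-pass response; ``fixed`` uses
        ``fixed_threshold`` as a fraction of the patch's peak response.
    min_area : px^2
        Components smaller than this are discarded as debris.
    focus_threshold : intensity/px on the [0, 1] scale
        Minimum mean gradient magnitude along a component's boundary;
        rejects heavily defocused bodies whose edges have washed out.
    score_floor : dimensionless
        Detections scoring below this are dropped.
    """

    smoothing_sigma_fine: float = 2.0
    smoothing_sigma_coarse: float = 15.0
    threshold_mode: str = "otsu"
    fixed_threshold: float = 0.25
    min_area: int = 150
    focus_threshold: float = 0.015
    score_floor: float = 0.2

    def __post_init__(self) -> None:
        if self.smoothing_sigma_fine >= self.smoothing_sigma_coarse:
            raise ValueError("smoothing_sigma_fine must be < smoothing_sigma_coarse")
        if self.min_area <= 0:
            raise ValueError("min_area must be positive")
        if self.threshold_mode not in {"otsu", "fixed"}:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0.0 <= self.fixed_threshold <= 1.0:
            raise ValueError("fixed_threshold must lie in [0, 1]")
        if not 0.0 <= self.score_floor <= 1.0:
            raise ValueError("score_floor must lie in [0, 1]")


@runtime_checkable
class Detector(Protocol):
    """The per-patch detection contract every backend implements."""

    def detect(
        self, patch: np.ndarray, origin: tuple[int, int] = (0, 0)
    ) -> list[Detection]:
        """Detect objects in one square patch.

        ``origin`` is the tile's top-left corner in global image
        coordinates; backends that work purely on pixels ignore it.
        Returned boxes are tile-local and lie inside the patch frame;
        output must be deterministic for a fixed patch and configuration.
        """
        ...


def _to_gray_unit(patch: np.ndarray) -> np.ndarray:
    """Collapse to grayscale and rescale to [0, 1] floats."""
    arr = np.asarray(patch, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    if not np.all(np.isfinite(arr)):
        raise ValueError("patch contains non-finite pixel values")
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


class ReferenceBlobDetector:
    """Difference-of-Gaussians blob detector with a boundary-focus gate.

    Organoids appear dark on a bright background, so the patch is
    inverted internally before the band-pass; the response is then
    ``smooth(sigma_fine) - smooth(sigma_coarse)`` of the inverted patch,
    positive inside dark bodies. The response is binarized, closed and
    hole-filled, and connected components become candidate detections.
    Small components, components whose boundary gradient falls below the
    focus threshold, and components with weak normalized contrast are
    discarded.
    """

    def __init__(self, config: DetectorConfig | None = None) -> None:
        self.config = config or DetectorConfig()

    def detect(
        self, patch: np.ndarray, origin: tuple[int, int] = (0, 0)
    ) -> list[Detection]:
        cfg = self.config
        if patch.ndim not in (2, 3) or patch.shape[0] != patch.shape[1]:
            raise ValueError(f"expected a square patch, got shape {patch.shape}")
        gray = _to_gray_unit(patch)
        inverted = 1.0 - gray

        response = ndi.gaussian_filter(
            inverted, cfg.smoothing_sigma_fine
        ) - ndi.gaussian_filter(inverted, cfg.smoothing_sigma_coarse)
        peak = float(response.max())
        if peak <= 0:
            return []

        if cfg.threshold_mode == "otsu":
            if np.ptp(response) == 0:
                return []
            thr = threshold_otsu(response)
            # Otsu on a near-empty patch splits noise; require a real peak
            if thr <= 0:
                return []
        else:
            thr = cfg.fixed_threshold * peak
        binary = response > thr

        binary = closing(binary, disk(3))
        binary = ndi.binary_fill_holes(binary)

        labels, n = ndi.label(binary)
        if n == 0:
            return []
        grad = np.hypot(*np.gradient(gray))

        detections: list[Detection] = []
        for lbl in range(1, n + 1):
            comp = labels == lbl
            area = int(comp.sum())
            if area < cfg.min_area:
                continue
            boundary = comp & ~ndi.binary_erosion(comp)
            if boundary.any() and float(grad[boundary].mean()) < cfg.focus_threshold:
                continue
            ys, xs = np.nonzero(comp)
            box = Box(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
            score = float(np.clip(response[comp].mean() / peak, 0.0, 1.0))
            if score < cfg.score_floor:
                continue
            detections.append(Detection(box=box, score=score))
        detections.sort(key=lambda d: (-d.score, d.box.as_tuple()))
        return detections


class OracleDetector:
    """Returns known ground-truth boxes clipped to the tile frame.

    Built from global ground-truth boxes; for each tile it emits, in
    tile-local coordinates with score 1.0, every ground-truth box that
    intersects the tile. Pure plumbing for tests: it proves the tiling,
    edge filtering and aggregation stages are lossless, independent of
    any real detector's quality.
    """

    def __init__(self, ground_truth_boxes: Sequence[Box]) -> None:
        self.boxes = list(ground_truth_boxes)

    def detect(
        self, patch: np.ndarray, origin: tuple[int, int] = (0, 0)
    ) -> list[Detection]:
        size = patch.shape[0]
        ox, oy = origin
        out: list[Detection] = []
        for b in self.boxes:
            local = Box(b.xmin - ox, b.ymin - oy, b.xmax - ox, b.ymax - oy)
            try:
                clipped = clip_box(local, size, size)
            except ValueError:
                continue
            out.append(Detection(box=clipped, score=1.0))
        return out


class SubprocessAdapterDetector:
    """Runs an external command per patch via a file-based exchange.

    The command is invoked as ``<command...> <patch.png> <out.csv>``; the
    patch is written as an 8-bit PNG and the command must write a CSV
    with header ``filename,width,height,class,xmin,ymin,xmax,ymax,score``
    (score optional, default 1.0). This keeps heavyweight ML runtimes out
    of this package while letting a trained network drive the pipeline.
    """

    def __init__(self, command: Sequence[str]) -> None:
        self.command = list(command)

    def detect(
        self, patch: np.ndarray, origin: tuple[int, int] = (0, 0)
    ) -> list[Detection]:
        import pandas as pd
        from PIL import Image

        size = patch.shape[0]
        with tempfile.TemporaryDirectory() as tmp:
            png = Path(tmp) / "patch.png"
            csv = Path(tmp) / "detections.csv"
            Image.fromarray(np.asarray(patch, dtype=np.uint8)).save(png)
            subprocess.run(
                [*self.command, str(png), str(csv)], check=True, capture_output=True
            )
            df = pd.read_csv(csv)
        out: list[Detection] = []
        for _, row in df.iterrows():
            box = clip_box(
                Box(int(row["xmin"]), int(row["ymin"]),
                    int(row["xmax"]), int(row["ymax"])),
                size,
                size,
            )
            score = float(row["score"]) if "score" in df.columns else 1.0
            out.append(Detection(box=box, score=score))
        return out


def score_threshold_filter(
    dets: Sequence[Detection], min_score: float
) -> list[Detection]:
    """Keep detections with score >= ``min_score``, order preserved."""
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score must lie in [0, 1], got {min_score}")
    return [d for d in dets if d.score >= min_score]
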