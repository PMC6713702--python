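"""Physical-unit morphometry under the inscribed-ellipse assumption.

Each organoid is assumed to be the ellipse inscribed in its bounding
box: semi-axes equal half the box sides. With a pixel scale ``s``
(microns per pixel), a ``w x h`` px box yields axis lengths ``w*s`` and
``h*s`` and projected area ``pi/4 * w*h * s^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import Box, Detection

__all__ = [
    "OrganoidMeasurement",
    "measure_organoid",
    "write_measurements_csv",
    "read_measurements_csv",
    "render_overlay",
    "CSV_COLUMNS",
]

CSV_COLUMNS = [
    "filename",
    "xmin",
    "ymin",
    "xmax",
    "ymax",
    "score",
    "major_axis_um",
    "minor_axis_um",
    "area_um2",
]


@dataclass(frozen=True)
class OrganoidMeasurement:
    box: Box
    major_axis_um: float
    minor_axis_um: float
    area_um2: float

    def __post_init__(self) -> None:
        if not self.major_axis_um >= self.minor_axis_um > 0:
            raise ValueError("axes must satisfy major >= minor > 0")
        expected = math.pi / 4.0 * self.major_axis_um * self.minor_axis_um
        if not math.isclose(self.area_um2, expected, rel_tol=1e-9):
            raise ValueError(
                f"area {self.area_um2} inconsistent with pi/4*major*minor "
                f"= {expected}"
            )


def measure_organoid(box: Box, microns_per_pixel: float) -> OrganoidMeasurement:
    """Measure one box as an inscribed ellipse in physical units."""
    if microns_per_pixel <= 0:
        raise ValueError(f"microns_per_pixel must be positive, got {microns_per_pixel}")
    w = box.width * microns_per_pixel
    h = box.height * microns_per_pixel
    return OrganoidMeasurement(
        box=box,
        major_axis_um=max(w, h),
        minor_axis_um=min(w, h),
        area_um2=math.pi / 4.0 * w * h,
    )


def write_measurements_csv(
    measurements: Sequence[OrganoidMeasurement],
    detections: Sequence[Detection],
    path: str | Path,
    filename: str = "",
) -> None:
    """Write aligned detections + measurements as one CSV row per organoid.

    Rows are ordered by descending score, ties broken by box coordinates,
    so output is deterministic regardless of detection order.
    """
    if len(measurements) != len(detections):
        raise ValueError("measurements and detections must align one-to-one")
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].score, detections[i].box.as_tuple()),
    )
    rows = []
    for i in order:
        d, m = detections[i], measurements[i]
        rows.append(
            {
                "filename": filename,
                "xmin": d.box.xmin,
                "ymin": d.box.ymin,
                "xmax": d.box.xmax,
                "ymax": d.box.ymax,
                "score": round(d.score, 6),
                "major_axis_um": round(m.major_axis_um, 4),
                "minor_axis_um": round(m.minor_axis_um, 4),
                "area_um2": round(m.area_um2, 4),
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    """Read a measurements CSV back as a DataFrame (column check only)."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurements CSV missing columns: {sorted(missing)}")
    return df


def render_overlay(
    image: np.ndarray,
    detections: Sequence[Detection],
    line_width: int = 2,
    draw_scores: bool = False,
) -> np.ndarray:
    """Draw detection boxes on a copy of the image as RGB.

    Each box becomes a ``line_width``-px rectangle outline; with
    ``draw_scores`` the confidence is printed beside the box. Pixels
    outside the drawn graphics are unchanged.
    """
    from PIL import Image, ImageDraw

    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    im = Image.fromarray(arr.astype(np.uint8))
    draw = ImageDraw.Draw(im)
    h, w = arr.shape[:2]
    for d in detections:
        b = d.box
        if b.xmin < 0 or b.ymin < 0 or b.xmax > w or b.ymax > h:
            raise ValueError(f"box {b.as_tuple()} outside the {w}x{h} frame")
        # -1: PIL rectangles are inclusive of both corners
        draw.rectangle(
            [b.xmin, b.ymin, b.xmax - 1, b.ymax - 1],
            outline=(255, 64, 32),
            width=line_width,
        )
        if draw_scores:
            draw.text(
                (b.xmin + line_width + 1, b.ymin + line_width + 1),
                f"{d.score:.2f}",
                fill=(255, 64, 32),
            )
    return np.asarray(im)
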