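"""Synthetic brightfield organoid scenes with exact ground truth.

Generates grayscale images that emulate low-magnification brightfield
views of organoids suspended in a hydrogel droplet: dark-rimmed elliptical
bodies with a lighter lumen on a bright background, with the confounders
such cultures show in practice — occlusion/overlap, out-of-focus
organoids, heterogeneous sizes, uneven illumination, and dense or sparse
fields. Every organoid's tight bounding box (computed from the rendered
mask before any blurring) is recorded, so detection and quantification
stages can be tested against exact ground truth without any real data.

The appearance model is deliberately simple (no physically based optics):
each organoid is a rotated ellipse whose transmittance dips to a dark rim
near its boundary and recovers partway in the lumen; organoids multiply
into the background, so overlapping bodies darken each other the way
occluding organoids do.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Box, iou

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "generate_fixture_dataset"]

# appearance constants (8-bit scale is applied at the end)
_BACKGROUND = 0.88      # bright-field background transmittance
_RIM_TRANSMITTANCE = 0.38   # darkest point of the organoid rim
_LUMEN_TRANSMITTANCE = 0.78  # interior recovers but stays below background
_RIM_FRACTION = 0.22    # rim occupies the outer fraction of the radial span


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    All stochastic choices are drawn from a single generator seeded with
    ``seed``, in a fixed order, so a spec fully determines its scene.
    """

    width: int = 1500
    height: int = 1125
    n_organoids: int = 20
    radius_range: tuple[float, float] = (15.0, 60.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.7)
    overlap_allowed: bool = True
    defocus_fraction: float = 0.0
    defocus_sigma: float = 6.0
    illumination_gradient: float = 0.0
    noise_sigma: float = 2.0
    seed: int = 0
    max_placement_retries: int = 1000

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if not 0 < lo <= hi < min(self.width, self.height) / 2:
            raise ValueError(f"radius_range {self.radius_range} out of bounds")
        for name in ("defocus_fraction", "illumination_gradient"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        elo, ehi = self.eccentricity_range
        if not 0.0 <= elo <= ehi < 1.0:
            raise ValueError(
                f"eccentricity_range {self.eccentricity_range} must lie in [0, 1)"
            )


@dataclass
class GroundTruth:
    """Exact per-organoid ground truth recorded at render time."""

    boxes: list[Box]
    in_focus_flags: list[bool]
    true_axes: list[tuple[float, float]]  # (semi-major, semi-minor) px


def _ellipse_geometry(
    rng: np.random.Generator, spec: SceneSpec
) -> tuple[float, float, float]:
    """Draw (semi-major a, semi-minor b, rotation angle) for one organoid."""
    a = rng.uniform(*spec.radius_range)
    ecc = rng.uniform(*spec.eccentricity_range)
    b = a * float(np.sqrt(1.0 - ecc**2))
    theta = rng.uniform(0.0, np.pi)
    return a, b, theta


def _render_organoid(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    a: float,
    b: float,
    theta: float,
) -> tuple[np.ndarray, np.ndarray, Box | None]:
    """Render one organoid's transmittance layer and binary mask.

    Works on a local window around the ellipse for speed; returns the
    full-frame transmittance (1.0 outside the organoid), the boolean
    mask, and the tight box of the mask (None if nothing rendered).
    """
    h, w = shape
    ct, st = np.cos(theta), np.sin(theta)
    # conservative bounding half-extents of the rotated ellipse
    dx = float(np.sqrt((a * ct) ** 2 + (b * st) ** 2))
    dy = float(np.sqrt((a * st) ** 2 + (b * ct) ** 2))
    x0 = max(int(np.floor(cx - dx)) - 2, 0)
    x1 = min(int(np.ceil(cx + dx)) + 3, w)
    y0 = max(int(np.floor(cy - dy)) - 2, 0)
    y1 = min(int(np.ceil(cy + dy)) + 3, h)
    if x1 <= x0 or y1 <= y0:
        return np.ones(shape, dtype=np.float64), np.zeros(shape, dtype=bool), None

    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # 0 at centre, 1 at boundary
    local_mask = r <= 1.0

    # radial transmittance profile: lumen plateau, dark rim, sharp edge
    t_local = np.ones_like(r)
    rim_start = 1.0 - _RIM_FRACTION
    lumen = r <= rim_start
    rim = local_mask & ~lumen
    t_local[lumen] = _LUMEN_TRANSMITTANCE
    # rim dips linearly to the darkest value at r = 1 - rim_fraction/2
    rr = (r[rim] - rim_start) / _RIM_FRACTION  # 0..1 across the rim
    depth = 1.0 - np.abs(2.0 * rr - 1.0)  # triangular profile
    t_local[rim] = _LUMEN_TRANSMITTANCE + depth * (
        _RIM_TRANSMITTANCE - _LUMEN_TRANSMITTANCE
    )

    transmittance = np.ones(shape, dtype=np.float64)
    transmittance[y0:y1, x0:x1] = t_local
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = local_mask

    ys, xs = np.nonzero(local_mask)
    if len(ys) == 0:
        return transmittance, mask, None
    box = Box(
        int(xs.min()) + x0,
        int(ys.min()) + y0,
        int(xs.max()) + x0 + 1,
        int(ys.max()) + y0 + 1,
    )
    return transmittance, mask, box


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; returns the 8-bit image and its ground truth.

    Raises
    ------
    RuntimeError
        If ``overlap_allowed`` is False and a non-overlapping placement
        cannot be found within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    canvas = np.full((h, w), _BACKGROUND, dtype=np.float64)

    boxes: list[Box] = []
    flags: list[bool] = []
    axes: list[tuple[float, float]] = []

    n_blurred = int(round(spec.defocus_fraction * spec.n_organoids))
    for k in range(spec.n_organoids):
        placed = False
        for _ in range(spec.max_placement_retries):
            a, b, theta = _ellipse_geometry(rng, spec)
            dx = float(np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2))
            dy = float(np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2))
            cx = rng.uniform(dx + 1, w - dx - 1)
            cy = rng.uniform(dy + 1, h - dy - 1)
            transmittance, mask, box = _render_organoid((h, w), cx, cy, a, b, theta)
            if box is None:
                continue
            if not spec.overlap_allowed and any(iou(box, prev) > 0 for prev in boxes):
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place organoid {k + 1}/{spec.n_organoids} without "
                f"overlap within {spec.max_placement_retries} retries"
            )
        in_focus = k >= n_blurred  # first n_blurred organoids are defocused
        if not in_focus and spec.defocus_sigma > 0:
            transmittance = gaussian_filter(
                transmittance, spec.defocus_sigma, mode="nearest"
            )
        canvas *= transmittance
        boxes.append(box)
        flags.append(in_focus)
        axes.append((a, b))

    if spec.illumination_gradient > 0:
        # linear field along a random direction, mean 1, peak-to-peak = g
        g = spec.illumination_gradient
        phi = rng.uniform(0.0, 2 * np.pi)
        xx = np.linspace(-0.5, 0.5, w)
        yy = np.linspace(-0.5, 0.5, h)
        field = 1.0 + g * (
            np.cos(phi) * xx[np.newaxis, :] + np.sin(phi) * yy[:, np.newaxis]
        )
        canvas *= field

    img = canvas * 255.0
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), GroundTruth(
        boxes=boxes, in_focus_flags=flags, true_axes=axes
    )


def generate_fixture_dataset(
    n_images: int,
    spec_template: SceneSpec,
    out_folder: str | Path,
    prefix: str = "scene",
    image_format: str = "png",
) -> Path:
    """Write ``n_images`` scenes plus one annotation CSV to a folder.

    Scene ``i`` uses seed ``spec_template.seed + i``. The CSV follows the
    published annotation schema (filename, width, height, class, xmin,
    ymin, xmax, ymax) with class ``organoid``. Returns the CSV path.
    """
    from . import dataset_io  # local import to avoid a cycle at import time

    out = Path(out_folder)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n_images):
        spec = replace(spec_template, seed=spec_template.seed + i)
        img, gt = generate_scene(spec)
        fname = f"{prefix}_{i:03d}.{image_format}"
        dataset_io.write_image(out / fname, img)
        for box in gt.boxes:
            records.append(
                dataset_io.AnnotationRecord(
                    filename=fname,
                    width=spec.width,
                    height=spec.height,
                    class_label="organoid",
                    box=box,
                )
            )
    csv_path = out / "annotations.csv"
    dataset_io.write_annotation_csv(records, csv_path)
    return csv_path
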