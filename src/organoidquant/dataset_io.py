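"""Annotation CSV I/O, image I/O, patchification and train/test splitting.

The annotation schema is one CSV row per bounding box::

    filename,width,height,class,xmin,ymin,xmax,ymax

with 0-based coordinates, origin at the image top-left, and the half-open
convention of :mod:`organoidquant.geometry`. A reader flag also accepts
the raw crowdsourcing dialect (xmin, ymin, width, height of the box),
converting it to corner form on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import Box

__all__ = [
    "AnnotationRecord",
    "read_annotation_csv",
    "write_annotation_csv",
    "read_image",
    "write_image",
    "patchify_for_annotation",
    "train_test_split",
]

CSV_COLUMNS = ["filename", "width", "height", "class", "xmin", "ymin", "xmax", "ymax"]
_EXPECTED_PATCH_SIZES = {300, 450}


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated bounding box within one image patch."""

    filename: str
    width: int
    height: int
    class_label: str
    box: Box

    def __post_init__(self) -> None:
        b = self.box
        if b.xmin < 0 or b.ymin < 0 or b.xmax > self.width or b.ymax > self.height:
            raise ValueError(
                f"box {b.as_tuple()} exceeds the {self.width}x{self.height} frame "
                f"of {self.filename!r}"
            )


def read_annotation_csv(
    path: str | Path, dialect: str = "corners", strict_sizes: bool = False
) -> list[AnnotationRecord]:
    """Read annotation records from a CSV file.

    Parameters
    ----------
    path : path
    dialect : {"corners", "xywh"}
        ``"corners"`` reads xmin/ymin/xmax/ymax columns as-is;
        ``"xywh"`` treats the last two coordinate columns (named width
        and height of the *box* in the raw crowdsourcing export) as box
        width/height and converts to corners.
    strict_sizes : bool
        If True, warn on patch sizes other than the published 300/450 px.

    Raises
    ------
    ValueError
        On a missing column, or on any row whose box violates the Box
        invariants — the error message lists the offending row numbers.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if dialect == "xywh":
        needed = {"filename", "width", "height", "class", "xmin", "ymin",
                  "box_width", "box_height"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
        df = df.assign(
            xmax=df["xmin"] + df["box_width"], ymax=df["ymin"] + df["box_height"]
        )
    elif dialect == "corners":
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    records: list[AnnotationRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        # data row number in the file (header is line 1)
        lineno = int(idx) + 2
        try:
            box = Box(int(row["xmin"]), int(row["ymin"]),
                      int(row["xmax"]), int(row["ymax"]))
            rec = AnnotationRecord(
                filename=str(row["filename"]),
                width=int(row["width"]),
                height=int(row["height"]),
                class_label=str(row["class"]),
                box=box,
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append((lineno, str(exc)))
            continue
        records.append(rec)
    if bad_rows:
        detail = "; ".join(f"row {n}: {msg}" for n, msg in bad_rows[:20])
        raise ValueError(f"{len(bad_rows)} invalid annotation row(s): {detail}")
    if strict_sizes:
        odd = {(r.width, r.height) for r in records} - {
            (s, s) for s in _EXPECTED_PATCH_SIZES
        }
        if odd:
            warnings.warn(
                f"patch sizes {sorted(odd)} differ from the published 300/450 px",
                stacklevel=2,
            )
    return records


def write_annotation_csv(records: list[AnnotationRecord], path: str | Path) -> None:
    """Write records to CSV in the published schema, input order preserved."""
    df = pd.DataFrame(
        [
            {
                "filename": r.filename,
                "width": r.width,
                "height": r.height,
                "class": r.class_label,
                "xmin": r.box.xmin,
                "ymin": r.box.ymin,
                "xmax": r.box.xmax,
                "ymax": r.box.ymax,
            }
            for r in records
        ],
        columns=CSV_COLUMNS,
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit TIFF or PNG image as a numpy array (H, W[, C])."""
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit image; TIFF via tifffile, everything else via Pillow."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image).save(path)


def patchify_for_annotation(
    image: np.ndarray,
    patch_sizes: list[int],
    source_name: str = "image",
) -> list[tuple[np.ndarray, str]]:
    """Cut non-overlapping grid-aligned patches for annotation jobs.

    For each requested size, full patches are taken from the top-left on
    a non-overlapping grid; partial strips at the bottom/right are
    discarded. Filenames encode source, size and grid position as
    ``{source}_s{size}_x{ix}_y{iy}.png``. Sizes larger than the image are
    skipped with a warning.
    """
    h, w = image.shape[:2]
    out: list[tuple[np.ndarray, str]] = []
    for size in patch_sizes:
        if size <= 0:
            raise ValueError(f"patch size must be positive, got {size}")
        if size > w or size > h:
            warnings.warn(
                f"image {w}x{h} smaller than patch size {size}; size skipped",
                stacklevel=2,
            )
            continue
        for iy in range(h // size):
            for ix in range(w // size):
                patch = image[iy * size : (iy + 1) * size, ix * size : (ix + 1) * size]
                out.append((patch, f"{source_name}_s{size}_x{ix}_y{iy}.png"))
    return out


def train_test_split(
    records: list[AnnotationRecord],
    test_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Split records into train/test at the level of filenames.

    All boxes belonging to one image patch land on the same side, so no
    patch leaks between splits. The number of test filenames is
    ``max(1, round(test_fraction * n_filenames))``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    filenames = sorted({r.filename for r in records})
    if len(filenames) < 2:
        raise ValueError("need at least 2 distinct filenames to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(filenames))
    n_test = max(1, int(round(test_fraction * len(filenames))))
    n_test = min(n_test, len(filenames) - 1)  # keep both sides non-empty
    test_names = {filenames[i] for i in order[:n_test]}
    train = [r for r in records if r.filename not in test_names]
    test = [r for r in records if r.filename in test_names]
    return train, test
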