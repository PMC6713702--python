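"""Sliding-window tiling of large images with bottom/right zero padding.

A large brightfield image is covered by an integer grid of square,
overlapping windows. The image is padded at the bottom and right edges
with black (zero) pixels so that the windows tile the padded frame
exactly; the grid is the minimal one for the chosen stride.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TileGrid", "plan_tile_grid", "pad_image", "extract_patches"]


@dataclass(frozen=True)
class TileGrid:
    """Plan for covering an image with a square sliding window.

    ``origins`` enumerates tile top-left corners row-major (left-to-right,
    then top-to-bottom). ``stride = patch_size - overlap``.
    """

    patch_size: int
    stride: int
    origins: tuple[tuple[int, int], ...]
    padded_width: int
    padded_height: int
    original_width: int
    original_height: int


def _n_windows(extent: int, patch_size: int, stride: int) -> int:
    # smallest n >= 1 with (n-1)*stride + patch_size >= extent
    if extent <= patch_size:
        return 1
    return 1 + -(-(extent - patch_size) // stride)  # ceil division


def plan_tile_grid(width: int, height: int, patch_size: int, overlap: int) -> TileGrid:
    """Plan the minimal integer window cover of a ``width x height`` image.

    Parameters
    ----------
    width, height : int
        Original image dimensions in pixels.
    patch_size : int
        Square window edge in pixels.
    overlap : int
        Overlap between adjacent windows in pixels; ``0 <= overlap <
        patch_size``. The stride is ``patch_size - overlap``.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    if not 0 <= overlap < patch_size:
        raise ValueError(
            f"overlap must satisfy 0 <= overlap < patch_size, got {overlap}"
        )
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    stride = patch_size - overlap
    n_x = _n_windows(width, patch_size, stride)
    n_y = _n_windows(height, patch_size, stride)
    padded_width = (n_x - 1) * stride + patch_size
    padded_height = (n_y - 1) * stride + patch_size
    origins = tuple(
        (ix * stride, iy * stride) for iy in range(n_y) for ix in range(n_x)
    )
    return TileGrid(
        patch_size=patch_size,
        stride=stride,
        origins=origins,
        padded_width=padded_width,
        padded_height=padded_height,
        original_width=width,
        original_height=height,
    )


def pad_image(image: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Zero-pad an image at the bottom and right to the grid's padded dims."""
    h, w = image.shape[:2]
    if (w, h) != (grid.original_width, grid.original_height):
        raise ValueError(
            f"image is {w}x{h} but grid was planned for "
            f"{grid.original_width}x{grid.original_height}"
        )
    pad_y = grid.padded_height - h
    pad_x = grid.padded_width - w
    pad_spec = [(0, pad_y), (0, pad_x)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad_spec, mode="constant", constant_values=0)


def extract_patches(
    padded: np.ndarray, grid: TileGrid
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Cut one ``patch_size x patch_size`` view per grid origin.

    Returns ``[(origin, patch), ...]`` in grid (row-major) order; patches
    are views into the padded array.
    """
    h, w = padded.shape[:2]
    if (w, h) != (grid.padded_width, grid.padded_height):
        raise ValueError(
            f"input is {w}x{h}; expected the padded frame "
            f"{grid.padded_width}x{grid.padded_height} (pad first)"
        )
    p = grid.patch_size
    return [((x, y), padded[y : y + p, x : x + p]) for x, y in grid.origins]
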