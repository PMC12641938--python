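"""Gaze coverage over a blue-baseline mask, and fixation heatmaps.

The capsulorhexis model region is labeled with an exact blue mask
(RGB (0, 0, 255)). A circular marker of fixed angular size (default 5
degrees of *diameter*) is painted at each fixation location, overwriting
the baseline with a non-blue cover color; coverage is then the count of
pixels that were blue in the baseline but are non-blue afterwards, over
the total pixel count of the baseline image. An alternative denominator
restricted to the blue region is available for sensitivity checks, since
the two conventions appear interchangeably in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.draw import disk

from .events import Fixation, GazeStream
from .geometry import ViewGeometry

__all__ = [
    "MaskImage",
    "CoverageResult",
    "BLUE",
    "paint_markers",
    "coverage_fraction",
    "fixation_heatmap",
    "read_mask_png",
    "write_mask_png",
]

BLUE = (0, 0, 255)
COVER_COLOR = (255, 64, 64)
DEFAULT_MARKER_SIZE = 5.0  # degrees


@dataclass(frozen=True)
class MaskImage:
    """An RGB raster with an exact-color blue label for the model region."""

    pixels: np.ndarray  # (H, W, 3) uint8
    blue_label: tuple[int, int, int] = BLUE

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if px.shape[0] == 0 or px.shape[1] == 0:
            raise ValueError("mask dimensions must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def blue_mask(self, tolerance: int = 0) -> np.ndarray:
        """Boolean map of blue-labeled pixels.

        ``tolerance`` is a per-channel radius in color space; 0 means exact
        match (the synthetic-fixture convention).
        """
        ref = np.array(self.blue_label, dtype=np.int16)
        diff = np.abs(self.pixels.astype(np.int16) - ref)
        return np.all(diff <= tolerance, axis=2)


@dataclass(frozen=True)
class CoverageResult:
    covered_pixels: int
    total_pixels: int

    @property
    def covered_fraction(self) -> float:
        return self.covered_pixels / self.total_pixels


def _marker_radius_px(marker_size: float, geometry: ViewGeometry, diameter: bool) -> float:
    deg_radius = marker_size / 2.0 if diameter else marker_size
    return deg_radius * geometry.px_per_deg


def paint_markers(
    mask: MaskImage,
    fixations: list[Fixation] | None,
    geometry: ViewGeometry,
    marker_size: float = DEFAULT_MARKER_SIZE,
    *,
    marker_is_diameter: bool = True,
    cover_color: tuple[int, int, int] = COVER_COLOR,
    stream: GazeStream | None = None,
) -> MaskImage:
    """Paint a circular marker at each gaze point; returns a new mask.

    By default markers are placed at fixation centroids with ``marker_size``
    interpreted as an angular *diameter* (a per-sample mode is available by
    passing ``stream`` instead of ``fixations``, and a radius interpretation
    via ``marker_is_diameter=False``). Markers falling partly or wholly
    outside the frame are clipped. The input mask is never modified.
    """
    if marker_size <= 0:
        raise ValueError("marker_size must be positive")
    if (fixations is None) == (stream is None):
        raise ValueError("provide exactly one of fixations or stream")
    r = _marker_radius_px(marker_size, geometry, marker_is_diameter)
    out = mask.pixels.copy()
    if stream is not None:
        xs, ys = geometry.deg_to_px(stream.x, stream.y)
        centers = zip(np.atleast_1d(ys), np.atleast_1d(xs))
    else:
        xy = [(geometry.deg_to_px(f.centroid_x, f.centroid_y)) for f in fixations]
        centers = ((float(y), float(x)) for x, y in xy)
    shape = (mask.height, mask.width)
    for cy, cx in centers:
        rr, cc = disk((float(cy), float(cx)), r, shape=shape)
        out[rr, cc] = cover_color
    return MaskImage(pixels=out, blue_label=mask.blue_label)


def coverage_fraction(
    baseline: MaskImage,
    painted: MaskImage,
    denominator: str = "frame",
    color_tolerance: int = 0,
) -> CoverageResult:
    """Covered pixels: blue in the baseline, non-blue after painting.

    ``denominator="frame"`` divides by the total pixel count of the baseline
    image (the reported convention); ``"blue_region"`` divides by the count
    of baseline blue pixels instead.
    """
    if (baseline.height, baseline.width) != (painted.height, painted.width):
        raise ValueError("baseline and painted masks must share dimensions")
    base_blue = baseline.blue_mask(color_tolerance)
    post_blue = painted.blue_mask(color_tolerance)
    covered = int(np.count_nonzero(base_blue & ~post_blue))
    if denominator == "frame":
        total = baseline.height * baseline.width
    elif denominator == "blue_region":
        total = int(np.count_nonzero(base_blue))
        if total == 0:
            raise ValueError("baseline has no blue pixels; blue_region denominator undefined")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return CoverageResult(covered_pixels=covered, total_pixels=total)


def fixation_heatmap(
    fixations: list[Fixation],
    geometry: ViewGeometry,
    kernel_sd: float,
    *,
    weight_by_duration: bool = False,
    normalize: bool = True,
) -> np.ndarray:
    """Gaussian-smoothed fixation density on the pixel grid.

    Each fixation deposits unit mass (or its duration, when weighted) at
    its pixel location; the grid is then smoothed with an isotropic
    Gaussian of ``kernel_sd`` degrees. With ``normalize=True`` the grid is
    scaled to a maximum of 1 for rendering; otherwise the raw grid is
    returned (total mass ~ deposited mass, minus boundary truncation).
    Empty input gives an all-zero grid.
    """
    from scipy.ndimage import gaussian_filter

    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    grid = np.zeros((geometry.height_px, geometry.width_px), dtype=float)
    if not fixations:
        return grid
    for f in fixations:
        px, py = geometry.deg_to_px(f.centroid_x, f.centroid_y)
        ix = int(round(float(px)))
        iy = int(round(float(py)))
        if 0 <= ix < geometry.width_px and 0 <= iy < geometry.height_px:
            grid[iy, ix] += f.duration if weight_by_duration else 1.0
    grid = gaussian_filter(grid, sigma=kernel_sd * geometry.px_per_deg, mode="constant")
    if normalize and grid.max() > 0:
        grid = grid / grid.max()
    return grid


def write_mask_png(mask: MaskImage, path) -> None:
    Image.fromarray(mask.pixels, mode="RGB").save(str(path), format="PNG")


def read_mask_png(path) -> MaskImage:
    with Image.open(str(path)) as im:
        return MaskImage(pixels=np.asarray(im.convert("RGB")))
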