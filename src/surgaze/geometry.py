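"""Scene geometry: the world-camera frame and the degrees <-> pixels map.

The scene camera records at 1280 x 720 px with a 100 degree diagonal field of
view. Gaze coordinates are expressed in degrees of visual angle in the scene
frame (origin top-left, y down, matching raster conventions); surfaces and
mask images are in pixels. A single linear scale factor converts between the
two (small-angle approximation — adequate because the frame subtends well
under the regime where tangent distortion matters for the metrics computed
here, and all reported saccade amplitudes are below one degree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ViewGeometry"]


@dataclass(frozen=True)
class ViewGeometry:
    """World-camera raster geometry and nominal gaze sampling rate.

    Parameters
    ----------
    width_px, height_px:
        Scene frame size in pixels.
    diagonal_fov:
        Diagonal field of view in degrees, in (0, 180).
    nominal_rate:
        Nominal gaze sampling rate in Hz (eye cameras, not the scene camera).
    """

    width_px: int = 1280
    height_px: int = 720
    diagonal_fov: float = 100.0
    nominal_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("width_px and height_px must be positive")
        if not 0.0 < self.diagonal_fov < 180.0:
            raise ValueError("diagonal_fov must lie in (0, 180) degrees")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")

    @property
    def diagonal_px(self) -> float:
        return math.hypot(self.width_px, self.height_px)

    @property
    def deg_per_px(self) -> float:
        """Linear degrees-per-pixel scale along any axis."""
        return self.diagonal_fov / self.diagonal_px

    @property
    def px_per_deg(self) -> float:
        return 1.0 / self.deg_per_px

    @property
    def width_deg(self) -> float:
        return self.width_px * self.deg_per_px

    @property
    def height_deg(self) -> float:
        return self.height_px * self.deg_per_px

    def deg_to_px(self, x_deg, y_deg):
        """Map scene-frame degree coordinates to pixel coordinates."""
        s = self.px_per_deg
        return np.asarray(x_deg) * s, np.asarray(y_deg) * s

    def px_to_deg(self, x_px, y_px):
        """Map pixel coordinates to scene-frame degree coordinates."""
        s = self.deg_per_px
        return np.asarray(x_px) * s, np.asarray(y_px) * s
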