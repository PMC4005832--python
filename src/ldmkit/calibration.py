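"""Physical-to-image calibration for the simulation-bed camera.

A known physical dimension of the rectangular treatment target (for the
reference setup, its 140 mm width) together with the matching extent in
pixels defines the conversion ratio ``C`` in mm/pixel.  The square
laser-emitting window of the applicator (12 mm side on the reference
device) then maps to a square template of ``template_side`` pixels that is
stamped onto the exposure-count grid for every detected laser spot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Tuple

import numpy as np

from ._util import round_half_up
from .exceptions import InvalidCalibrationError

__all__ = [
    "CalibrationModel",
    "calibrate_from_extents",
    "calibrate_from_corners",
    "mm_to_px",
    "px_to_mm",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Conversion between physical (mm) and image (pixel) space.

    Parameters
    ----------
    physical_extent_mm
        Length in mm of a known target dimension.
    pixel_extent_px
        The same dimension measured in image pixels.
    laser_window_mm
        Side of the square laser-emitting window in mm.
    """

    physical_extent_mm: float
    pixel_extent_px: float
    laser_window_mm: float

    def __post_init__(self) -> None:
        for name in ("physical_extent_mm", "pixel_extent_px", "laser_window_mm"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidCalibrationError(
                    f"{name} must be strictly positive, got {value!r}"
                )

    @property
    def conversion_ratio(self) -> float:
        """``C`` in mm per pixel (stored at full precision)."""
        return self.physical_extent_mm / self.pixel_extent_px

    @property
    def template_side(self) -> int:
        """Side of the square template in pixels (laser window / C, half-up)."""
        side = round_half_up(self.laser_window_mm / self.conversion_ratio)
        return max(int(side), 1)


def calibrate_from_extents(
    physical_extent_mm: float, pixel_extent_px: float, laser_window_mm: float
) -> CalibrationModel:
    """Build a :class:`CalibrationModel` from one known physical/pixel pair.

    Examples
    --------
    >>> cal = calibrate_from_extents(140.0, 397.0, 12.0)
    >>> round(cal.conversion_ratio, 2), cal.template_side
    (0.35, 34)
    """
    return CalibrationModel(physical_extent_mm, pixel_extent_px, laser_window_mm)


def mm_to_px(x_mm, cal: CalibrationModel):
    """Convert a length (or array of lengths) from mm to pixels."""
    return np.asarray(x_mm, dtype=float) / cal.conversion_ratio if np.ndim(x_mm) else float(x_mm) / cal.conversion_ratio


def px_to_mm(x_px, cal: CalibrationModel):
    """Convert a length (or array of lengths) from pixels to mm."""
    return np.asarray(x_px, dtype=float) * cal.conversion_ratio if np.ndim(x_px) else float(x_px) * cal.conversion_ratio


def calibrate_from_corners(
    corner_shots: Mapping[str, Iterable[Tuple[float, float]]],
    physical_extent_mm: float,
    laser_window_mm: float,
) -> CalibrationModel:
    """Estimate calibration from corner-marking laser shots.

    ``corner_shots`` maps the corner names ``top_left``, ``top_right``,
    ``bottom_left``, ``bottom_right`` to one or more detected centroids
    (row, col) fired at that corner of the target.  The centroids of each
    corner are averaged, and the pixel extent is the mean of the top and
    bottom edge lengths, matched against ``physical_extent_mm`` (the target
    width).
    """
    required = {"top_left", "top_right", "bottom_left", "bottom_right"}
    missing = required - set(corner_shots)
    if missing:
        raise InvalidCalibrationError(f"missing corner shots: {sorted(missing)}")
    means = {
        name: np.mean(np.asarray(list(pts), dtype=float).reshape(-1, 2), axis=0)
        for name, pts in corner_shots.items()
    }
    top = np.linalg.norm(means["top_right"] - means["top_left"])
    bottom = np.linalg.norm(means["bottom_right"] - means["bottom_left"])
    pixel_extent = (top + bottom) / 2.0
    if pixel_extent <= 0:
        raise InvalidCalibrationError("corner shots yield a zero pixel extent")
    return CalibrationModel(physical_extent_mm, pixel_extent, laser_window_mm)
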