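"""Reconstruction of the laser distribution map (LDM).

The LDM is an integer grid L(m, n) over the target area counting how many
laser exposures covered each pixel.  Every detected spot contributes a
constant-valued square template (the laser-emitting window scaled to
pixels) centered at its centroid; overlapping templates accumulate, so the
maximum grid value alpha is the worst redundancy of delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from ._util import round_half_up
from .exceptions import OutOfBoundsError

__all__ = ["LDM", "overlay_template", "synthesize_ldm", "template_bounds"]


@dataclass
class LDM:
    """Exposure-count grid plus the ordered spot sequence that produced it."""

    grid: np.ndarray
    spots: List[Tuple[float, float]] = field(default_factory=list)
    template_side: int = 1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("LDM grid must be two-dimensional")
        if self.template_side < 1:
            raise ValueError("template_side must be >= 1")

    @property
    def alpha(self) -> int:
        """Maximum redundancy: highest exposure count in the grid."""
        return int(self.grid.max()) if self.grid.size else 0

    @property
    def beta(self) -> int:
        """Number of laser spots."""
        return len(self.spots)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape


def template_bounds(center: int, side: int, limit: int) -> Tuple[int, int]:
    """Clipped [start, stop) covered by a template along one axis.

    The template spans ``ceil((side-1)/2)`` cells before and
    ``floor((side-1)/2)`` cells after the center cell (for side 34: 17
    before, 16 after), clipped to ``[0, limit)``.
    """
    before = side // 2  # == ceil((side-1)/2)
    after = side - 1 - before
    return max(center - before, 0), min(center + after + 1, limit)


def _stamp(grid: np.ndarray, centroid: Tuple[float, float], side: int) -> None:
    rows, cols = grid.shape
    r = round_half_up(centroid[0])
    c = round_half_up(centroid[1])
    if not (0 <= r < rows and 0 <= c < cols):
        raise OutOfBoundsError(
            f"centroid {tuple(centroid)} (cell ({r}, {c})) outside {rows}x{cols} grid"
        )
    r0, r1 = template_bounds(r, side, rows)
    c0, c1 = template_bounds(c, side, cols)
    grid[r0:r1, c0:c1] += 1


def overlay_template(ldm: LDM, centroid: Tuple[float, float]) -> LDM:
    """Return a new LDM with one more template stamped at ``centroid``.

    Cells of the template falling outside the grid are silently clipped
    (spots fired at the target edge are legal); a centroid whose rounded
    cell is outside the grid raises :class:`OutOfBoundsError`.
    """
    grid = ldm.grid.copy()
    _stamp(grid, centroid, ldm.template_side)
    return LDM(grid=grid, spots=[*ldm.spots, (float(centroid[0]), float(centroid[1]))],
               template_side=ldm.template_side)


def synthesize_ldm(
    spots: Sequence[Tuple[float, float]],
    dims: Tuple[int, int],
    template_side: int,
) -> LDM:
    """Fold template overlays over ``spots`` on a zero-initialized grid.

    Parameters
    ----------
    spots
        Ordered (row, col) centroids in target pixel coordinates.
    dims
        (rows, cols) of the target grid.
    template_side
        Side of the square template in pixels.
    """
    rows, cols = int(dims[0]), int(dims[1])
    if rows <= 0 or cols <= 0:
        raise ValueError("grid dimensions must be positive")
    grid = np.zeros((rows, cols), dtype=np.int32)
    kept: List[Tuple[float, float]] = []
    for i, spot in enumerate(spots):
        try:
            _stamp(grid, spot, template_side)
        except OutOfBoundsError as exc:
            raise OutOfBoundsError(f"spot {i}: {exc}") from None
        kept.append((float(spot[0]), float(spot[1])))
    return LDM(grid=grid, spots=kept, template_side=int(template_side))
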