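"""Laser-spot localization within a laser-exposed frame.

Frames are binarized at 30% of their maximum grayscale; the largest
8-connected white cluster is taken as the true laser spot (reflections off
the bed frame can appear as smaller secondary clusters), and its unweighted
centroid in continuous (row, col) pixel coordinates is the spot position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage import measure

from .exceptions import NoSpotError

__all__ = ["SpotDetection", "binarize", "largest_cluster", "centroid", "detect_spot"]


@dataclass(frozen=True)
class SpotDetection:
    """One detected laser spot."""

    frame_index: int
    centroid: Tuple[float, float]
    cluster_area: int


def binarize(frame: np.ndarray, rel_threshold: float = 0.30) -> np.ndarray:
    """Threshold a frame at ``rel_threshold`` times its maximum (inclusive).

    Raises
    ------
    NoSpotError
        If the frame is entirely zero (nothing to threshold against).
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    frame = np.asarray(frame)
    peak = frame.max()
    if peak <= 0:
        raise NoSpotError("frame contains no nonzero pixel")
    return frame >= rel_threshold * peak


def largest_cluster(mask: np.ndarray) -> np.ndarray:
    """Pixel coordinates (n, 2) of the largest 8-connected component.

    Ties in area are broken by choosing the component containing the
    lexicographically smallest (row, col) pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    n_labels = labels.max()
    if n_labels == 0:
        raise NoSpotError("mask contains no foreground pixel")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = np.flatnonzero(counts == counts.max())
    if best.size > 1:
        # first foreground pixel in raster scan order == lexicographic min
        flat = labels.ravel()
        first = [np.flatnonzero(flat == lab)[0] for lab in best]
        chosen = best[int(np.argmin(first))]
    else:
        chosen = best[0]
    return np.argwhere(labels == chosen)


def centroid(component: np.ndarray) -> Tuple[float, float]:
    """Unweighted mean (row, col) of a pixel set given as an (n, 2) array."""
    component = np.asarray(component, dtype=float).reshape(-1, 2)
    if component.shape[0] == 0:
        raise NoSpotError("empty component")
    r, c = component.mean(axis=0)
    return float(r), float(c)


def detect_spot(
    frame: np.ndarray, frame_index: int = 0, rel_threshold: float = 0.30
) -> SpotDetection:
    """Binarize, pick the largest cluster, and return its centroid."""
    mask = binarize(frame, rel_threshold)
    component = largest_cluster(mask)
    return SpotDetection(
        frame_index=frame_index,
        centroid=centroid(component),
        cluster_area=int(component.shape[0]),
    )
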