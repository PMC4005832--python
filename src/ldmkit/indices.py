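"""Performance indices computed from an LDM and its spot sequence.

Four indices summarize one session:

* ``delta0`` — percent of the target never exposed (omission error),
  (A0 - A1) / A0 x 100, with A0 the target pixel count and A_k the number
  of pixels exposed at least k times.
* ``deltaz`` — percent measure of redundant exposure, sum over k >= 2 of
  A_k / A0 x 100; counts every extra dose, so it may exceed 100%.
* ``mu`` — mean Euclidean distance between temporally consecutive spot
  centroids, converted to mm.  A perfectly abutting delivery makes mu
  equal the laser-window side (12 mm on the reference device).
* ``upsilon`` — coefficient of variation (sample std / mean) of the
  per-spot nearest-neighbour distances: the randomness of delivery.  Both
  the raw ratio and the x100 percent form are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import cdist

from .calibration import CalibrationModel
from .exceptions import (
    DegenerateConfigurationError,
    InsufficientSpotsError,
)
from .ldm_synthesis import LDM

__all__ = [
    "CoverageProfile",
    "PerformanceIndices",
    "coverage_areas",
    "delta0",
    "deltaz",
    "consecutive_distances",
    "nearest_neighbor_distances",
    "mu",
    "upsilon",
    "compute_indices",
]


@dataclass(frozen=True)
class CoverageProfile:
    """Pixel census of an LDM: A0 = M*N and A_k for k = 1..alpha."""

    A0: int
    A: np.ndarray  # A[k-1] = count of pixels with value >= k

    @property
    def alpha(self) -> int:
        return len(self.A)


@dataclass(frozen=True)
class PerformanceIndices:
    """The four indices plus spot count beta and max redundancy alpha."""

    delta0: float
    deltaz: float
    mu_mm: float
    upsilon_pct: float
    upsilon_ratio: float
    beta: int
    alpha: int

    def as_dict(self, ndigits: int | None = None) -> dict:
        out = {
            "delta0": self.delta0,
            "deltaz": self.deltaz,
            "mu": self.mu_mm,
            "upsilon": self.upsilon_pct,
            "upsilon_ratio": self.upsilon_ratio,
            "beta": self.beta,
            "alpha": self.alpha,
        }
        if ndigits is not None:
            out = {
                k: (round(v, ndigits) if isinstance(v, float) else v)
                for k, v in out.items()
            }
        return out


def coverage_areas(ldm: LDM) -> CoverageProfile:
    """Count pixels exposed at least k times, for k = 1..alpha."""
    grid = ldm.grid
    alpha = int(grid.max()) if grid.size else 0
    counts = np.array(
        [int(np.count_nonzero(grid >= k)) for k in range(1, alpha + 1)], dtype=int
    )
    return CoverageProfile(A0=int(grid.size), A=counts)


def delta0(profile: CoverageProfile) -> float:
    """Percent of the target never exposed."""
    if profile.A0 <= 0:
        raise ValueError("A0 must be positive")
    A1 = int(profile.A[0]) if profile.alpha >= 1 else 0
    return (profile.A0 - A1) / profile.A0 * 100.0


def deltaz(profile: CoverageProfile) -> float:
    """Percent measure of redundant exposure (multiplicities k >= 2)."""
    if profile.A0 <= 0:
        raise ValueError("A0 must be positive")
    redundant = int(profile.A[1:].sum()) if profile.alpha >= 2 else 0
    return redundant / profile.A0 * 100.0


def _spots_array(spots: Sequence[Tuple[float, float]]) -> np.ndarray:
    arr = np.asarray(spots, dtype=float).reshape(-1, 2)
    if arr.shape[0] < 2:
        raise InsufficientSpotsError(
            f"need at least 2 spots, got {arr.shape[0]}"
        )
    return arr


def consecutive_distances(spots: Sequence[Tuple[float, float]]) -> np.ndarray:
    """Euclidean distances between temporally consecutive centroids."""
    arr = _spots_array(spots)
    return np.linalg.norm(np.diff(arr, axis=0), axis=1)


def nearest_neighbor_distances(spots: Sequence[Tuple[float, float]]) -> np.ndarray:
    """For each spot, the distance to its nearest other spot."""
    arr = _spots_array(spots)
    d = cdist(arr, arr)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def _conversion(cal: Union[CalibrationModel, float]) -> float:
    return cal.conversion_ratio if isinstance(cal, CalibrationModel) else float(cal)


def mu(
    spots: Sequence[Tuple[float, float]], cal: Union[CalibrationModel, float]
) -> float:
    """Mean consecutive-spot distance in mm (mean(d_c) x C)."""
    return float(np.mean(consecutive_distances(spots))) * _conversion(cal)


def upsilon(spots: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """Nearest-neighbour CV as (percent, raw ratio).

    Uses the sample (n-1) standard deviation.  Raises
    :class:`DegenerateConfigurationError` when all spots coincide
    (zero mean distance).
    """
    dn = nearest_neighbor_distances(spots)
    mean = float(dn.mean())
    if mean <= 0.0:
        raise DegenerateConfigurationError("all spots coincide; upsilon undefined")
    ratio = float(dn.std(ddof=1)) / mean
    return 100.0 * ratio, ratio


def compute_indices(
    ldm: LDM, cal: Union[CalibrationModel, float]
) -> PerformanceIndices:
    """Bundle all four indices for one session's LDM."""
    profile = coverage_areas(ldm)
    ups_pct, ups_ratio = upsilon(ldm.spots)
    return PerformanceIndices(
        delta0=delta0(profile),
        deltaz=deltaz(profile),
        mu_mm=mu(ldm.spots, cal),
        upsilon_pct=ups_pct,
        upsilon_ratio=ups_ratio,
        beta=ldm.beta,
        alpha=ldm.alpha,
    )
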