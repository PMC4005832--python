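"""End-to-end processing of one session: video in, LDM and indices out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .calibration import CalibrationModel
from .frame_extraction import FrameStack, LaserEvent, extract_laser_frames
from .indices import PerformanceIndices, compute_indices
from .ldm_synthesis import LDM, synthesize_ldm
from .spot_detection import SpotDetection, detect_spot

__all__ = ["PipelineResult", "process_session"]


@dataclass
class PipelineResult:
    """Everything produced while processing one session."""

    ldm: LDM
    indices: PerformanceIndices
    detections: List[SpotDetection]
    events: List[LaserEvent]


def process_session(
    stack: FrameStack,
    cal: CalibrationModel,
    target_dims_px: Tuple[int, int],
    margin_px: int = 0,
    rejection_ratio: float = 0.30,
    rel_threshold: float = 0.30,
) -> PipelineResult:
    """Extract exposures, detect spots, build the LDM and score it.

    ``target_dims_px`` is the (rows, cols) size of the designated target
    area; ``margin_px`` is the border of the camera frame around the
    target, subtracted from detected centroids to map frame coordinates
    into target coordinates.  Centroids are clipped into the target grid
    (spots fired at the edge are legal and their templates clip).
    """
    pairs = extract_laser_frames(stack, rejection_ratio=rejection_ratio)
    detections = [
        detect_spot(frame, ev.frame_index, rel_threshold=rel_threshold)
        for frame, ev in pairs
    ]
    rows, cols = target_dims_px
    centroids = [
        (
            float(np.clip(det.centroid[0] - margin_px, 0, rows - 1)),
            float(np.clip(det.centroid[1] - margin_px, 0, cols - 1)),
        )
        for det in detections
    ]
    ldm = synthesize_ldm(centroids, target_dims_px, cal.template_side)
    indices = compute_indices(ldm, cal)
    return PipelineResult(
        ldm=ldm,
        indices=indices,
        detections=detections,
        events=[ev for _, ev in pairs],
    )
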