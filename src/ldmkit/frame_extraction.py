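"""Selection of laser-exposed frames from a session recording.

A fired laser pulse lights up the otherwise dark scene, so the per-frame
mean grayscale trace shows one sharp peak per exposure.  Air fires (pulses
fired with the applicator lifted off the surface, typically at directional
changes during spot-by-spot work) raise the overall brightness only
mildly; peaks below 30% of the normal peak height are rejected as invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .exceptions import EmptyInputError

__all__ = [
    "FrameStack",
    "LaserEvent",
    "mean_intensity_trace",
    "detect_events",
    "filter_air_fires",
    "extract_laser_frames",
    "default_min_separation",
]


@dataclass
class FrameStack:
    """Ordered grayscale frames of one session.

    ``frames`` is an (n_frames, rows, cols) integer array; ``frame_rate``
    is in Hz.
    """

    frames: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class LaserEvent:
    """One candidate laser exposure located on the intensity trace."""

    frame_index: int
    peak_height: float
    valid: bool = True


def mean_intensity_trace(stack: FrameStack) -> np.ndarray:
    """Per-frame mean grayscale of the stack.

    Raises
    ------
    EmptyInputError
        If the stack has no frames.
    """
    if len(stack) == 0:
        raise EmptyInputError("frame stack is empty")
    return stack.frames.mean(axis=(1, 2))


def default_min_separation(frame_rate: float, max_pulse_rate: float = 2.0) -> int:
    """Minimum frame separation preventing one pulse being counted twice."""
    return max(1, int(np.floor(frame_rate / (2.0 * max_pulse_rate))))


def detect_events(
    trace: Sequence[float],
    baseline_quantile: float = 0.5,
    min_separation_frames: int = 1,
    rel_epsilon: float = 0.05,
) -> List[LaserEvent]:
    """Locate candidate laser exposures as peaks of the intensity trace.

    A frame is a candidate when the trace exceeds
    ``quantile + rel_epsilon * (max - quantile)``; each contiguous
    supra-threshold run yields one event at the run's maximum (first frame
    of a plateau).  Events closer than ``min_separation_frames`` are merged,
    keeping the taller peak.  A flat trace yields no events.
    """
    values = np.asarray(trace, dtype=float)
    if values.size == 0:
        raise EmptyInputError("intensity trace is empty")
    baseline = np.quantile(values, baseline_quantile)
    threshold = baseline + rel_epsilon * (values.max() - baseline)
    above = values > threshold

    events: List[LaserEvent] = []
    n = values.size
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        peak = i + int(np.argmax(values[i : j + 1]))  # argmax: first of plateau
        events.append(LaserEvent(peak, float(values[peak])))
        i = j + 1

    if min_separation_frames > 1 and events:
        merged = [events[0]]
        for ev in events[1:]:
            if ev.frame_index - merged[-1].frame_index < min_separation_frames:
                if ev.peak_height > merged[-1].peak_height:
                    merged[-1] = ev
            else:
                merged.append(ev)
        events = merged
    return events


def filter_air_fires(
    events: Sequence[LaserEvent],
    rejection_ratio: float = 0.30,
    baseline: float = 0.0,
) -> List[LaserEvent]:
    """Flag air-fire events whose peak falls below the rejection cutoff.

    The reference ("normal") peak height is the median over all candidate
    events, measured above ``baseline``; an event is invalid when its
    height above baseline is below ``rejection_ratio`` times the reference.
    All events are returned, in temporal order, with ``valid`` flags set;
    the operation is idempotent because the reference is recomputed from
    the full candidate list on every call.
    """
    if not 0.0 < rejection_ratio < 1.0:
        raise ValueError("rejection_ratio must lie in (0, 1)")
    events = list(events)
    if not events:
        return []
    heights = np.array([ev.peak_height for ev in events], dtype=float) - baseline
    reference = float(np.median(heights))
    cutoff = rejection_ratio * reference
    return [
        replace(ev, valid=bool(h >= cutoff)) for ev, h in zip(events, heights)
    ]


def extract_laser_frames(
    stack: FrameStack,
    baseline_quantile: float = 0.5,
    rejection_ratio: float = 0.30,
    min_separation_frames: int | None = None,
    rel_epsilon: float = 0.05,
) -> List[Tuple[np.ndarray, LaserEvent]]:
    """Return (frame, event) pairs for every valid laser exposure.

    Composes :func:`mean_intensity_trace`, :func:`detect_events` and
    :func:`filter_air_fires`; air-fire heights are measured above the
    candidacy baseline of the trace.
    """
    trace = mean_intensity_trace(stack)
    if min_separation_frames is None:
        min_separation_frames = default_min_separation(stack.frame_rate)
    events = detect_events(
        trace,
        baseline_quantile=baseline_quantile,
        min_separation_frames=min_separation_frames,
        rel_epsilon=rel_epsilon,
    )
    baseline = float(np.quantile(trace, baseline_quantile))
    flagged = filter_air_fires(events, rejection_ratio, baseline=baseline)
    return [(stack.frames[ev.frame_index], ev) for ev in flagged if ev.valid]
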