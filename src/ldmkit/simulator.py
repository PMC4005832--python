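"""Synthetic operator sessions: ground-truth spot sequences and rendered video.

The simulator stands in for the physical simulation bed.  An operator is
modeled as traversing a serpentine (boustrophedon) raster of intended
positions over the rectangular target — the natural strategy for covering
the target uniformly with either technique — with isotropic Gaussian
positional jitter, occasional omissions and double exposures.  Spot-by-spot
(SBS) sessions may additionally fire in the air at row turn-arounds, which
appears on camera as a dim, spotless frame.

Rendering emulates the camera view: a dark, mildly noisy background; for
each pulse a bright square the size of the laser-emitting window, placed
with sub-pixel coverage weighting and Gaussian-blurred (silicone-sheet
scattering plus the camera's point-spread); air-fire frames as a uniform
brightness lift at 25% of a pulse frame's mean signal, below the 30%
validity cutoff by construction.  The rendered frame is larger than the
target area by a margin of one template side on every edge, mirroring the
camera's view of the full bed around the marked target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import CalibrationModel, calibrate_from_extents
from .exceptions import DegenerateRasterError
from .frame_extraction import FrameStack

__all__ = [
    "SBS",
    "SLIDING",
    "SimulationConfig",
    "GroundTruth",
    "default_calibration",
    "preset_config",
    "generate_spot_sequence",
    "render_frames",
    "simulate_session",
    "run_study_design",
]

SBS = "sbs"
SLIDING = "sliding"

#: Reference-device calibration: 140 mm of target width == 397 px,
#: 12 mm laser-emitting window (template side 34 px).
def default_calibration() -> CalibrationModel:
    return calibrate_from_extents(140.0, 397.0, 12.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Operator-behaviour and rendering parameters for one session.

    Distances are mm, rates Hz, rendering lengths px.  Defaults mirror the
    reference study conditions: a 140 x 90 mm target, 12 mm intended pitch
    (the laser-window side), pulses at 2 Hz recorded at 30 Hz.
    """

    technique: str = SBS
    target_extent_mm: Tuple[float, float] = (140.0, 90.0)  # (width, height)
    intended_pitch_mm: float = 12.0
    jitter_sigma_mm: float = 1.2
    omission_prob: float = 0.05
    double_prob: float = 0.05
    air_fire_prob: float = 0.3
    frame_rate: float = 30.0
    pulse_rate: float = 2.0
    peak_intensity: float = 200.0
    blur_sigma_px: float = 2.0
    noise_level: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in (SBS, SLIDING):
            raise ValueError(f"unknown technique {self.technique!r}")
        for name in ("omission_prob", "double_prob", "air_fire_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.intended_pitch_mm <= 0 or self.jitter_sigma_mm < 0:
            raise ValueError("pitch must be positive and jitter non-negative")
        if self.pulse_rate > self.frame_rate:
            raise ValueError("pulse_rate must not exceed frame_rate")


#: Technique presets: sliding shows higher baseline jitter and no air
#: fires; SBS places discretely and air-fires at turn-arounds.  The
#: post-feedback phase shrinks jitter and omissions (operator training).
_PRESETS = {
    SBS: dict(jitter_sigma_mm=1.2, omission_prob=0.05, double_prob=0.03,
              air_fire_prob=0.3),
    SLIDING: dict(jitter_sigma_mm=2.0, omission_prob=0.08, double_prob=0.03,
                  air_fire_prob=0.0),
}
_FEEDBACK_JITTER_FACTOR = 0.7
_FEEDBACK_OMISSION_FACTOR = 0.6


def preset_config(
    technique: str, feedback: str = "pre", seed: int = 0, **overrides
) -> SimulationConfig:
    """Study-design preset for one technique and feedback phase."""
    if technique not in _PRESETS:
        raise ValueError(f"unknown technique {technique!r}")
    params = dict(_PRESETS[technique])
    if feedback == "post":
        params["jitter_sigma_mm"] *= _FEEDBACK_JITTER_FACTOR
        params["omission_prob"] *= _FEEDBACK_OMISSION_FACTOR
    elif feedback != "pre":
        raise ValueError("feedback must be 'pre' or 'post'")
    params.update(overrides)
    return SimulationConfig(technique=technique, seed=seed, **params)


@dataclass
class GroundTruth:
    """Realized spot sequence and frame timeline of one simulated session."""

    spots_mm: np.ndarray        # (beta, 2) (row, col) mm in target coords
    spots_px: np.ndarray        # (beta, 2) (row, col) px in target coords
    pulse_frames: np.ndarray    # (beta,) frame index of each pulse
    air_fire_frames: np.ndarray # frame indices of air fires
    n_frames: int
    margin_px: int              # border around the target in rendered frames
    config: SimulationConfig
    calibration: CalibrationModel

    @property
    def beta(self) -> int:
        return self.spots_mm.shape[0]

    @property
    def spots_frame_px(self) -> np.ndarray:
        """Spot centroids in rendered-frame pixel coordinates."""
        return self.spots_px + self.margin_px


def _raster_intents(config: SimulationConfig) -> List[Tuple[np.ndarray, bool]]:
    """Serpentine intended positions; flags mark the last spot of a row."""
    width, height = config.target_extent_mm
    pitch = config.intended_pitch_mm
    if pitch > width or pitch > height:
        raise DegenerateRasterError(
            f"pitch {pitch} mm exceeds target extent {config.target_extent_mm}"
        )
    cols = np.arange(pitch / 2.0, width, pitch)
    rows = np.arange(pitch / 2.0, height, pitch)
    intents: List[Tuple[np.ndarray, bool]] = []
    for i, y in enumerate(rows):
        xs = cols if i % 2 == 0 else cols[::-1]
        for j, x in enumerate(xs):
            intents.append((np.array([y, x]), j == len(xs) - 1))
    return intents


def generate_spot_sequence(
    config: SimulationConfig, cal: CalibrationModel | None = None
) -> GroundTruth:
    """Draw one session's realized spot sequence and frame timeline.

    Deterministic given ``config.seed``.  Each intended raster position is
    skipped with ``omission_prob``, fired twice with ``double_prob`` (each
    firing gets an independent jitter draw), and jittered by an isotropic
    Gaussian of ``jitter_sigma_mm``.  For the SBS technique an air fire is
    inserted after a row's last spot with ``air_fire_prob``.
    """
    cal = cal or default_calibration()
    rng = np.random.default_rng(config.seed)
    width, height = config.target_extent_mm

    events: List[object] = []  # (row, col) arrays for pulses, "air" markers
    for intent, row_end in _raster_intents(config):
        if rng.random() >= config.omission_prob:
            n_fires = 2 if rng.random() < config.double_prob else 1
            for _ in range(n_fires):
                pos = intent + rng.normal(0.0, config.jitter_sigma_mm, size=2)
                pos[0] = np.clip(pos[0], 0.0, height)
                pos[1] = np.clip(pos[1], 0.0, width)
                events.append(pos)
        if (
            row_end
            and config.technique == SBS
            and rng.random() < config.air_fire_prob
        ):
            events.append("air")
    spacing = max(1, int(round(config.frame_rate / config.pulse_rate)))
    lead = spacing
    spots_mm: List[np.ndarray] = []
    pulse_frames: List[int] = []
    air_frames: List[int] = []
    for slot, ev in enumerate(events):
        frame = lead + slot * spacing
        if isinstance(ev, str):
            air_frames.append(frame)
        else:
            spots_mm.append(ev)
            pulse_frames.append(frame)
    n_frames = lead + len(events) * spacing + spacing

    spots_mm_arr = (
        np.asarray(spots_mm, dtype=float).reshape(-1, 2)
        if spots_mm
        else np.empty((0, 2))
    )
    spots_px = spots_mm_arr / cal.conversion_ratio
    return GroundTruth(
        spots_mm=spots_mm_arr,
        spots_px=spots_px,
        pulse_frames=np.asarray(pulse_frames, dtype=int),
        air_fire_frames=np.asarray(air_frames, dtype=int),
        n_frames=n_frames,
        margin_px=cal.template_side,
        config=config,
        calibration=cal,
    )


def _coverage_profile(center: float, half: float, start: int, stop: int) -> np.ndarray:
    """Fractional coverage of pixels [start, stop) by [center-half, center+half).

    Pixel i spans [i - 0.5, i + 0.5) in index coordinates (center at i).
    """
    idx = np.arange(start, stop, dtype=float)
    lo = np.maximum(idx - 0.5, center - half)
    hi = np.minimum(idx + 0.5, center + half)
    return np.clip(hi - lo, 0.0, 1.0)


def _render_stamp(
    shape: Tuple[int, int],
    center: np.ndarray,
    side_px: float,
    peak: float,
    blur_sigma: float,
) -> Tuple[slice, slice, np.ndarray]:
    """Blurred, coverage-weighted square patch and its placement slices."""
    half = side_px / 2.0
    pad = int(np.ceil(4.0 * blur_sigma)) + 1
    r0 = max(int(np.floor(center[0] - half)) - pad, 0)
    r1 = min(int(np.ceil(center[0] + half)) + pad + 1, shape[0])
    c0 = max(int(np.floor(center[1] - half)) - pad, 0)
    c1 = min(int(np.ceil(center[1] + half)) + pad + 1, shape[1])
    cov_r = _coverage_profile(center[0], half, r0, r1)
    cov_c = _coverage_profile(center[1], half, c0, c1)
    patch = peak * np.outer(cov_r, cov_c)
    if blur_sigma > 0:
        patch = gaussian_filter(patch, blur_sigma, mode="constant")
    return slice(r0, r1), slice(c0, c1), patch


def render_frames(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    cal: CalibrationModel | None = None,
) -> FrameStack:
    """Render a session's 8-bit grayscale frame stack from its ground truth."""
    config = config or truth.config
    cal = cal or truth.calibration
    C = cal.conversion_ratio
    width, height = config.target_extent_mm
    target_rows = int(round(height / C))
    target_cols = int(round(width / C))
    m = truth.margin_px
    shape = (target_rows + 2 * m, target_cols + 2 * m)
    side_px = cal.laser_window_mm / C

    # mean signal a pulse adds to a frame; air fires lift the whole frame
    # uniformly to 25% of that, below the 30% validity cutoff
    pulse_mean_signal = side_px * side_px * config.peak_intensity / (shape[0] * shape[1])
    air_value = 0.25 * pulse_mean_signal

    pulse_at = {int(f): i for i, f in enumerate(truth.pulse_frames)}
    air_at = set(int(f) for f in truth.air_fire_frames)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E55]))
    frames = np.empty((truth.n_frames, *shape), dtype=np.uint8)
    centers = truth.spots_frame_px
    for t in range(truth.n_frames):
        if config.noise_level > 0:
            img = rng.standard_normal(shape, dtype=np.float32) * config.noise_level
        else:
            img = np.zeros(shape, dtype=np.float32)
        if t in pulse_at:
            rs, cs, patch = _render_stamp(
                shape, centers[pulse_at[t]], side_px,
                config.peak_intensity, config.blur_sigma_px,
            )
            img[rs, cs] += patch.astype(np.float32)
        elif t in air_at:
            img += air_value
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameStack(frames=frames, frame_rate=config.frame_rate)


def simulate_session(
    config: SimulationConfig, cal: CalibrationModel | None = None
) -> Tuple[FrameStack, GroundTruth]:
    """Generate ground truth and rendered frames for one session."""
    truth = generate_spot_sequence(config, cal)
    return render_frames(truth), truth


def run_study_design(
    configs: Sequence[SimulationConfig], cal: CalibrationModel | None = None
) -> List[Tuple[FrameStack, GroundTruth]]:
    """Simulate a multi-session dataset (e.g. techniques x feedback phases)."""
    if len(configs) == 0:
        raise ValueError("at least one session config is required")
    return [simulate_session(cfg, cal) for cfg in configs]
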