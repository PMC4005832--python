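"""Reading and writing the tool's on-disk formats.

Frame stacks are exchanged as numerically ordered image directories
(PNG/TIFF), multi-page TIFFs, or ``.npy`` arrays; video containers
(AVI/MP4) are decoded through imageio when an ffmpeg plugin is available.
Spot tables are CSV, LDMs are ``.npz`` (lossless) with an optional 16-bit
PNG rendering, calibration is YAML, and index reports are JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel, calibrate_from_extents
from .frame_extraction import FrameStack
from .indices import PerformanceIndices
from .ldm_synthesis import LDM
from .spot_detection import SpotDetection

__all__ = [
    "load_frame_stack",
    "save_frame_stack",
    "spots_to_csv",
    "spots_from_csv",
    "save_ldm",
    "load_ldm",
    "load_calibration",
    "save_calibration",
    "save_indices",
]

_IMAGE_EXT = {".png", ".tif", ".tiff", ".bmp"}
_VIDEO_EXT = {".avi", ".mp4", ".mov", ".mkv"}


def _numeric_sort_key(path: Path):
    nums = re.findall(r"\d+", path.stem)
    return (int(nums[-1]) if nums else 0, path.name)


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:  # collapse any color channels
        img = img.mean(axis=-1)
    return img


def load_frame_stack(path: str | Path, frame_rate: float = 30.0) -> FrameStack:
    """Load a session recording as a grayscale :class:`FrameStack`.

    ``path`` may be a directory of numerically ordered images, a
    multi-page TIFF, a ``.npy`` array of shape (n, rows, cols), or a video
    container (requires an imageio ffmpeg plugin).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXT),
            key=_numeric_sort_key,
        )
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        frames = np.stack([_to_gray(iio.imread(f)) for f in files])
    elif path.suffix.lower() == ".npy":
        frames = np.load(path)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        frames = _to_gray(iio.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    elif path.suffix.lower() in _VIDEO_EXT:
        try:
            frames = np.stack([_to_gray(f) for f in iio.imiter(path)])
        except Exception as exc:  # plugin missing or codec unsupported
            raise RuntimeError(
                f"could not decode video {path}; install an imageio ffmpeg "
                "plugin or export the recording as an image sequence"
            ) from exc
    else:
        raise ValueError(f"unsupported frame source: {path}")
    return FrameStack(frames=np.asarray(frames), frame_rate=frame_rate)


def save_frame_stack(stack: FrameStack, out_dir: str | Path) -> Path:
    """Write a stack as zero-padded PNG frames; returns the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(stack))))
    for i, frame in enumerate(stack.frames):
        iio.imwrite(out_dir / f"frame_{i:0{width}d}.png", frame.astype(np.uint8))
    return out_dir


def spots_to_csv(spots: Sequence[SpotDetection], path: str | Path) -> None:
    """Write detections as CSV (0-based row/col coordinates)."""
    df = pd.DataFrame(
        {
            "frame_index": [s.frame_index for s in spots],
            "row": [s.centroid[0] for s in spots],
            "col": [s.centroid[1] for s in spots],
            "area": [s.cluster_area for s in spots],
        }
    )
    df.to_csv(path, index=False)


def spots_from_csv(path: str | Path) -> list[SpotDetection]:
    df = pd.read_csv(path)
    return [
        SpotDetection(int(r.frame_index), (float(r.row), float(r.col)), int(r.area))
        for r in df.itertuples()
    ]


def save_ldm(ldm: LDM, path: str | Path, png: bool = False) -> None:
    """Save an LDM as ``.npz``; optionally also a 16-bit grayscale PNG."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        grid=ldm.grid,
        spots=np.asarray(ldm.spots, dtype=float).reshape(-1, 2),
        template_side=ldm.template_side,
    )
    if png:
        iio.imwrite(path.with_suffix(".png"), ldm.grid.astype(np.uint16))


def load_ldm(path: str | Path) -> LDM:
    data = np.load(Path(path).with_suffix(".npz"))
    return LDM(
        grid=data["grid"],
        spots=[tuple(s) for s in data["spots"]],
        template_side=int(data["template_side"]),
    )


def save_calibration(cal: CalibrationModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "physical_extent_mm": cal.physical_extent_mm,
                "pixel_extent_px": cal.pixel_extent_px,
                "laser_window_mm": cal.laser_window_mm,
            },
            fh,
        )


def load_calibration(path: str | Path) -> CalibrationModel:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return calibrate_from_extents(
        data["physical_extent_mm"], data["pixel_extent_px"], data["laser_window_mm"]
    )


def save_indices(
    indices: PerformanceIndices, path: str | Path, **provenance
) -> None:
    """Write an index report as JSON; extra kwargs become provenance fields."""
    report = indices.as_dict()
    if provenance:
        report["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
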