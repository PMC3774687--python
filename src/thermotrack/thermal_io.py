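"""Thermal frame stacks and tracking/annotation tables.

Frames are single-channel temperature rasters in abstract linear units
(monotone in degrees Celsius; the camera's count-to-temperature calibration is
irrelevant to the pipeline, which is threshold- and distribution-based).
Coordinates are 0-based with ``x`` = column and ``y`` = row, at pixel centres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_FPS = 30.0

TRACK_COLUMNS = [
    "frame",
    "mouse_id",
    "nose_x",
    "nose_y",
    "genitals_x",
    "genitals_y",
    "centroid_x",
    "centroid_y",
    "length",
    "flag",
]

ANNOTATION_COLUMNS = ["frame", "ref_id", "target_id", "label"]


class VideoReadError(Exception):
    """Base class for thermal-video ingest failures."""


class MissingVideoError(VideoReadError):
    """The requested path does not exist."""


class EmptyVideoError(VideoReadError):
    """The path exists but yields zero frames."""


class FrameDimensionError(VideoReadError):
    """Frames in one video do not share a single raster size."""


@dataclass
class ThermalFrame:
    """One thermal raster.

    Parameters
    ----------
    values : ndarray of float, shape (H, W)
        Temperature samples in linear units.
    index : int
        0-based frame ordinal within the video.
    period : float
        Seconds per frame (1 / fps).
    """

    values: np.ndarray
    index: int
    period: float = 1.0 / DEFAULT_FPS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("frame values must be a 2D raster")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame values must be finite")
        if self.index < 0:
            raise ValueError("frame index must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _frames_from_arrays(
    arrays: Sequence[np.ndarray], scale: float, offset: float, period: float
) -> list[ThermalFrame]:
    if len(arrays) == 0:
        raise EmptyVideoError("video contains zero frames")
    shape = arrays[0].shape
    frames = []
    for i, arr in enumerate(arrays):
        if arr.shape != shape:
            raise FrameDimensionError(
                f"frame {i} has shape {arr.shape}, expected {shape}"
            )
        frames.append(
            ThermalFrame(arr.astype(np.float64) * scale + offset, index=i, period=period)
        )
    return frames


def read_video(
    path: str | Path,
    *,
    scale: float = 1.0,
    offset: float = 0.0,
    fps: float = DEFAULT_FPS,
) -> list[ThermalFrame]:
    """Read a thermal video from a multi-page TIFF or a directory of frames.

    A directory is read as its lexicographically sorted 16-bit PNG/PGM/TIFF
    files. Raw integer counts are mapped to temperature units linearly:
    ``units = counts * scale + offset``.

    Raises
    ------
    MissingVideoError, EmptyVideoError, FrameDimensionError
    """
    path = Path(path)
    period = 1.0 / fps
    if not path.exists():
        raise MissingVideoError(f"no such video path: {path}")
    if path.is_dir():
        import imageio.v3 as iio

        names = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in {".png", ".pgm", ".tif", ".tiff"}
        )
        arrays = [np.asarray(iio.imread(p)) for p in names]
        return _frames_from_arrays(arrays, scale, offset, period)
    import tifffile

    with tifffile.TiffFile(os.fspath(path)) as tif:
        arrays = [page.asarray() for page in tif.pages]
    return _frames_from_arrays(arrays, scale, offset, period)


def write_video(
    frames: Sequence[ThermalFrame],
    path: str | Path,
    *,
    scale: float = 1.0,
    offset: float = 0.0,
) -> None:
    """Write frames as a multi-page 16-bit TIFF, inverting the read mapping."""
    import tifffile

    stack = np.stack(
        [np.round((f.values - offset) / scale).clip(0, 65535) for f in frames]
    ).astype(np.uint16)
    tifffile.imwrite(os.fspath(path), stack)


def write_tracks(poses_per_frame, path: str | Path) -> None:
    """Write per-frame per-mouse poses as a tracking CSV.

    ``poses_per_frame`` is a sequence over frames; each element is either a
    list of :class:`~thermotrack.temporal_watershed.MousePose` or a tuple
    ``(frame_index, flag)`` for frames skipped by re-initialisation, which are
    retained as rows with empty keypoints and the flag set.
    """
    rows = []
    for entry in poses_per_frame:
        if isinstance(entry, tuple):
            frame_idx, flag = entry
            rows.append([frame_idx, -1] + [np.nan] * 7 + [flag])
            continue
        for pose in entry:
            rows.append(
                [
                    pose.frame,
                    pose.mouse_id,
                    pose.nose[0],
                    pose.nose[1],
                    pose.genitals[0],
                    pose.genitals[1],
                    pose.centroid[0],
                    pose.centroid[1],
                    pose.length,
                    pose.flag,
                ]
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.8f")


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a tracking CSV written by :func:`write_tracks`."""
    return pd.read_csv(path, dtype={"flag": str})


def write_annotations(labels: pd.DataFrame, path: str | Path) -> None:
    """Write per-frame pair behaviour annotations (frame, ref_id, target_id, label)."""
    labels.loc[:, ANNOTATION_COLUMNS].to_csv(path, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# Re-exported here so the IO module presents the full surface (frame stacks,
# tables, and synthetic generation) in one place.
from .synth import ScenarioSpec, GroundTruth, generate_scenario  # noqa: E402,F401
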