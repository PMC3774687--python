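"""Foreground extraction and blob analysis.

The threshold separating warm mouse bodies from the cooler arena is chosen
once, during an initialisation phase, by scanning candidate temperatures drawn
from the empirical temperature distribution of a window of consecutive frames:
a candidate is feasible when every frame in the window shows exactly the
expected number of connected foreground components with a plausible total
area. After thresholding, a morphological opening with a 5 px linear
structuring element at 0, 45 and 90 degrees removes tails and speckle; 8-connected
components give the blobs. Count mismatches are corrected by iterative
dilation (too many blobs) or deferred to the temporal watershed (too few).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .thermal_io import ThermalFrame


class InitialisationError(Exception):
    """No window of frames admitted a feasible foreground threshold."""


@dataclass
class DetectionConfig:
    n_mice: int = 2
    min_mouse_area: int = 120  # expected size of the smallest mouse, px^2
    init_window: int = 90  # frames used for threshold initialisation
    opening_length: int = 5  # linear structuring-element length, px
    area_upper_factor: float = 4.0  # upper area bound multiple of min_mouse_area
    max_dilations: int = 5
    max_candidates: int = 512

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.min_mouse_area < 1 or self.init_window < 1:
            raise ValueError("n_mice, min_mouse_area, init_window must be >= 1")
        if self.opening_length % 2 == 0:
            raise ValueError("opening_length must be odd")


@dataclass
class ForegroundMask:
    mask: np.ndarray  # bool, same dims as frame
    threshold_used: float


@dataclass
class Blob:
    pixels: np.ndarray  # (N, 2) array of (row, col)
    area: int
    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


def _linear_selems(length: int) -> list[np.ndarray]:
    """5 px (by default) linear structuring elements at 0, 45 and 90 degrees."""
    horiz = np.ones((1, length), dtype=bool)
    vert = np.ones((length, 1), dtype=bool)
    diag = np.eye(length, dtype=bool)
    return [horiz, diag, vert]


def segment_foreground(frame: ThermalFrame, threshold: float) -> ForegroundMask:
    """Threshold the frame and remove tails/speckle by oriented openings.

    A pixel stays foreground iff it survives the opening under at least one of
    the three oriented linear structuring elements (their union), so bodies of
    any orientation keep their area while 1-2 px tails vanish.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    raw = frame.values > threshold
    out = np.zeros_like(raw)
    for selem in _linear_selems(5):
        out |= ndimage.binary_opening(raw, structure=selem)
    return ForegroundMask(mask=out, threshold_used=float(threshold))


def extract_blobs(mask: ForegroundMask) -> list[Blob]:
    """8-connected components of the mask, sorted by descending area."""
    labels = measure.label(mask.mask, connectivity=2)
    blobs = []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        blobs.append(
            Blob(
                pixels=region.coords,
                area=int(region.area),
                centroid=(float(cx), float(cy)),
                bbox=tuple(region.bbox),
            )
        )
    blobs.sort(key=lambda b: -b.area)
    return blobs


def remove_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop unfeasibly small connected structures (stray tail/speckle remnants).

    Candidate mouse bodies are never smaller than a fraction of the smallest
    expected mouse; anything below ``min_area`` is not a possible mouse and is
    removed before blob analysis.
    """
    if min_area <= 1 or not mask.any():
        return mask
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = np.flatnonzero(areas >= min_area)
    return np.isin(labels, keep)


def _count_components(mask: np.ndarray, min_area: int = 0) -> int:
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if min_area > 1 and n:
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        return int(np.count_nonzero(areas >= min_area))
    return n


def _window_feasible(
    frames: Sequence[ThermalFrame], threshold: float, cfg: DetectionConfig
) -> bool:
    lo = cfg.n_mice * cfg.min_mouse_area
    hi = cfg.n_mice * cfg.area_upper_factor * cfg.min_mouse_area
    small = cfg.min_mouse_area // 2
    for f in frames:
        fg = segment_foreground(f, threshold)
        mask = remove_small_components(fg.mask, small)
        area = int(mask.sum())
        if not (lo <= area <= hi):
            return False
        if _count_components(mask) != cfg.n_mice:
            return False
    return True


def _candidates(frames: Sequence[ThermalFrame], max_candidates: int) -> np.ndarray:
    """Midpoints between consecutive unique temperatures, subsampled."""
    values = np.unique(np.concatenate([f.values.ravel() for f in frames]))
    if values.size < 2:
        return values
    mids = 0.5 * (values[:-1] + values[1:])
    if mids.size > max_candidates:
        idx = np.linspace(0, mids.size - 1, max_candidates).round().astype(int)
        mids = mids[np.unique(idx)]
    return mids


def estimate_threshold(
    frames: Sequence[ThermalFrame], cfg: DetectionConfig
) -> float:
    """Estimate the foreground temperature threshold on an initial window.

    Candidate thresholds are the sorted unique temperature values of the
    window, subsampled to at most ``cfg.max_candidates`` and scanned from high
    to low; the first feasible candidate is kept, so the threshold settles
    just below the coolest body temperature, far above the background noise.
    The window of ``init_window`` consecutive frames slides from the start of
    the video until one admits a feasible candidate.

    Raises :class:`InitialisationError` if no window before the video end
    satisfies the condition.
    """
    if len(frames) < cfg.init_window:
        raise InitialisationError(
            f"need at least {cfg.init_window} frames, got {len(frames)}"
        )
    last_start = len(frames) - cfg.init_window
    for start in range(last_start + 1):
        window = frames[start : start + cfg.init_window]
        cands = _candidates(window, cfg.max_candidates)
        # coarse screen on the middle frame keeps the scan cheap
        mid = window[len(window) // 2]
        small = cfg.min_mouse_area // 2
        for thr in cands[::-1]:
            fg = segment_foreground(mid, thr)
            if _count_components(fg.mask, small) != cfg.n_mice:
                continue
            if _window_feasible(window, thr, cfg):
                return float(thr)
    raise InitialisationError(
        f"no feasible threshold found; last window tried started at frame {last_start}"
    )


def reconcile_blob_count(
    mask: ForegroundMask, cfg: DetectionConfig
) -> tuple[ForegroundMask, str]:
    """Correct the blob count towards the expected number of mice.

    Returns ``(mask', status)`` with status one of ``ok`` (count matches,
    possibly after up to ``max_dilations`` corrective 3x3 dilations),
    ``merged_for_watershed`` (fewer blobs than mice: touching bodies, left to
    the temporal watershed) or ``reinit`` (uncorrectable: the caller should
    re-initialise on following frames).
    """
    small = cfg.min_mouse_area // 2
    cleaned = remove_small_components(mask.mask, small)
    if cleaned is not mask.mask:
        mask = ForegroundMask(mask=cleaned, threshold_used=mask.threshold_used)
    n = _count_components(mask.mask)
    if n == cfg.n_mice:
        return mask, "ok"
    if n < cfg.n_mice:
        return mask, "merged_for_watershed"
    m = mask.mask
    structure = np.ones((3, 3), dtype=bool)
    for _ in range(cfg.max_dilations):
        m = ndimage.binary_dilation(m, structure=structure)
        n = _count_components(m)
        if n <= cfg.n_mice:
            status = "ok" if n == cfg.n_mice else "merged_for_watershed"
            return ForegroundMask(mask=m, threshold_used=mask.threshold_used), status
    return mask, "reinit"
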