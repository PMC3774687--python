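"""The 13-measurement spatio-temporal feature vector for ordered mouse pairs.

Three categories: relative position (four keypoint distances between the
reference and target mouse, plus the distance from the reference to its
*nearest* conspecific), shape of the reference mouse (first Hu moment and
area), and movement of the reference mouse (centroid displacement at six
signed time offsets covering past and future, a multi-scale proxy for speed
and acceleration). All distances are in pixels: the classifier is trained
from examples at the same scale, so no physical calibration is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .temporal_watershed import MousePose

#: fixed column order of the feature table
FEATURE_NAMES = [
    "head2head",
    "head2body",
    "head2genitals",
    "genitals2genitals",
    "body2body_nearest",
    "hu1_ref",
    "area_ref",
    "disp_m15",
    "disp_m5",
    "disp_m1",
    "disp_p1",
    "disp_p5",
    "disp_p15",
]

FEATURE_COLUMNS = ["frame", "ref_id", "target_id"] + FEATURE_NAMES


@dataclass(frozen=True)
class OffsetScheme:
    """Signed frame offsets for the movement features (past negative)."""

    offsets: tuple[int, ...] = (-15, -5, -1, 1, 5, 15)

    def __post_init__(self) -> None:
        if len(self.offsets) != 6:
            raise ValueError("exactly six movement offsets required")
        if 0 in self.offsets:
            raise ValueError("offsets must be non-zero")
        if not (min(self.offsets) < 0 < max(self.offsets)):
            raise ValueError("offsets must include past and future")


def relative_position_features(
    ref: MousePose, target: MousePose, all_poses: Sequence[MousePose]
) -> np.ndarray:
    """head2head, head2body, head2genitals, genitals2genitals, body2body_nearest.

    The first four are keypoint distances between the ordered pair;
    body2body_nearest is the centroid distance from the reference to the
    closest *other* mouse, whichever it is.
    """
    h2h = float(np.linalg.norm(ref.nose - target.nose))
    h2b = float(np.linalg.norm(ref.nose - target.centroid))
    h2g = float(np.linalg.norm(ref.nose - target.genitals))
    g2g = float(np.linalg.norm(ref.genitals - target.genitals))
    others = [p for p in all_poses if p.mouse_id != ref.mouse_id]
    b2b = min(float(np.linalg.norm(ref.centroid - p.centroid)) for p in others)
    return np.array([h2h, h2b, h2g, g2g, b2b])


def shape_features(ref: MousePose) -> np.ndarray:
    """(hu1, area) of the reference mouse."""
    if ref.area == 0:
        raise ValueError("shape features require a non-empty shape")
    return np.array([ref.hu1, float(ref.area)])


def movement_features(
    centroid_track: np.ndarray, t: int, scheme: OffsetScheme = OffsetScheme()
) -> np.ndarray:
    """Centroid displacement magnitudes at the six signed offsets.

    Offsets falling outside the track are clamped to the first/last frame, so
    every frame stays classifiable at the cost of attenuated edge estimates.
    """
    n = centroid_track.shape[0]
    c0 = centroid_track[t]
    out = np.empty(len(scheme.offsets))
    for k, off in enumerate(scheme.offsets):
        tt = min(max(t + off, 0), n - 1)
        out[k] = float(np.linalg.norm(c0 - centroid_track[tt]))
    return out


def build_pair_features(
    poses_per_frame: Sequence,
    scheme: OffsetScheme = OffsetScheme(),
    frame_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Feature table with one row per ordered pair per valid frame.

    ``poses_per_frame`` is the tracker output (:attr:`TrackResult.poses`):
    per-frame pose lists, with flagged frames as ``(index, status)`` tuples.
    Flagged frames contribute no rows. Movement features are computed on each
    mouse's centroid track over valid frames (per-identity), with clamping at
    gaps and edges.
    """
    valid = [
        (i, entry)
        for i, entry in enumerate(poses_per_frame)
        if not isinstance(entry, tuple)
    ]
    if frame_range is not None:
        lo, hi = frame_range
        valid = [(i, e) for i, e in valid if lo <= i < hi]
    if not valid:
        return pd.DataFrame(columns=FEATURE_COLUMNS)

    m_count = len(valid[0][1])
    tracks = {
        m: np.stack([entry[m].centroid for _, entry in valid]) for m in range(m_count)
    }

    rows = []
    for row_t, (frame_idx, poses) in enumerate(valid):
        for ref in poses:
            move = movement_features(tracks[ref.mouse_id], row_t, scheme)
            for target in poses:
                if target.mouse_id == ref.mouse_id:
                    continue
                rel = relative_position_features(ref, target, poses)
                shp = shape_features(ref)
                rows.append(
                    [frame_idx, ref.mouse_id, target.mouse_id]
                    + list(np.concatenate([rel, shp, move]))
                )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df[["frame", "ref_id", "target_id"]] = df[["frame", "ref_id", "target_id"]].astype(int)
    return df
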