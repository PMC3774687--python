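"""Identity preservation across frames.

Under normal conditions identities follow a greedy minimum-distance assignment
between the 6-D keypoint vectors of consecutive frames. A continuously fitted
Student's t model of the first Hu moment of accepted shapes flags frames where
two or more shapes deviate from the typical body-shape distribution (the
signature of a watershed seed overflowing onto a neighbour); on such frames
the assignment switches to heat-signature matching, where per-mouse
temperature-sample buffers are compared to the current shapes with the
two-sample Kolmogorov-Smirnov statistic. The KS statistic is used raw as an
assignment cost: it is distribution-free and monotone in evidence of mismatch.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .thermal_io import ThermalFrame
from .blob_detection import (
    DetectionConfig,
    ForegroundMask,
    estimate_threshold,
    segment_foreground,
    extract_blobs,
    reconcile_blob_count,
    remove_small_components,
    _count_components,
)


def _count_blobs(fg: ForegroundMask) -> int:
    return _count_components(fg.mask)
from .temporal_watershed import (
    MousePose,
    WatershedConfig,
    TouchingMiceError,
    bootstrap_poses,
    em_segment,
    correct_orientation,
)

KS_SENTINEL = 2.0  # above the KS statistic's upper bound of 1


def distance_matrix(
    prev_poses: Sequence[MousePose], cur_poses: Sequence[MousePose]
) -> np.ndarray:
    """Pairwise Euclidean distances between 6-D position vectors.

    Entry (i, j) is the distance between previous mouse i and current shape j.
    """
    if len(prev_poses) != len(cur_poses):
        raise ValueError("previous and current pose counts must match")
    zp = np.stack([p.z for p in prev_poses])
    zc = np.stack([p.z for p in cur_poses])
    return np.linalg.norm(zp[:, None, :] - zc[None, :, :], axis=2)


def greedy_assign(costs: np.ndarray) -> np.ndarray:
    """Global-minimum-first assignment on a square cost matrix.

    Repeatedly fixes the globally smallest remaining entry and removes its row
    and column. Ties break on the smallest row index, then the smallest column
    index. Returns ``perm`` with ``perm[i] = j``: identity i maps to shape j.
    """
    c = np.asarray(costs, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("cost matrix must be square")
    if not np.all(np.isfinite(c)):
        raise ValueError("cost matrix must be finite")
    n = c.shape[0]
    work = c.copy()
    perm = np.full(n, -1, dtype=int)
    for _ in range(n):
        flat = np.argmin(work)  # row-major: ties resolve to smallest row, then col
        i, j = divmod(int(flat), n)
        perm[i] = j
        work[i, :] = np.inf
        work[:, j] = np.inf
    return perm


@dataclass
class ShapeStatistics:
    """Running Student's t model of the first Hu moment of accepted shapes."""

    alpha: float = 0.01
    min_shapes: int = 100
    refit_every: int = 100
    record: list[float] = field(default_factory=list)
    _params: tuple[float, float, float] | None = None  # (df, loc, scale)
    _fitted_at: int = 0

    def add(self, hu1_values: Sequence[float]) -> None:
        self.record.extend(float(v) for v in hu1_values)
        if (
            len(self.record) >= self.min_shapes
            and len(self.record) - self._fitted_at >= self.refit_every
        ):
            self._refit()

    def _refit(self) -> None:
        data = np.asarray(self.record)
        if np.ptp(data) < 1e-15:
            # degenerate record: fall back to a point model
            self._params = (10.0, float(data.mean()), max(float(data.std()), 1e-9))
        else:
            df, loc, scale = stats.t.fit(data)
            self._params = (float(df), float(loc), max(float(scale), 1e-12))
        self._fitted_at = len(self.record)

    @property
    def ready(self) -> bool:
        return len(self.record) >= self.min_shapes

    def tail_probability(self, hu1: float) -> float:
        if self._params is None:
            self._refit()
        df, loc, scale = self._params
        cdf = stats.t.cdf(hu1, df, loc=loc, scale=scale)
        return 2.0 * min(cdf, 1.0 - cdf)


def shape_sanity_check(
    shape_stats: ShapeStatistics, hu1_values: Sequence[float]
) -> tuple[np.ndarray, bool]:
    """Flag shapes deviating from the fitted Hu-moment distribution.

    A mouse is flagged when the two-sided tail probability of its hu1 under
    the fitted t distribution falls below alpha. The global misdetection state
    (the trigger to switch to heat matching) is raised only when two or more
    mice are flagged in the same frame. With insufficient history all flags
    are false (cold start).
    """
    m = len(hu1_values)
    if not shape_stats.ready:
        return np.zeros(m, dtype=bool), False
    flags = np.array(
        [shape_stats.tail_probability(v) < shape_stats.alpha for v in hu1_values]
    )
    return flags, int(flags.sum()) >= 2


@dataclass
class HeatSignature:
    """Temperature-sample buffer for one mouse over the last B frames."""

    mouse_id: int
    buffer_frames: int = 9  # ~0.3 s at 30 fps
    _frames: deque = field(default_factory=deque)

    def add(self, samples: np.ndarray) -> None:
        self._frames.append(np.asarray(samples, dtype=float))
        while len(self._frames) > self.buffer_frames:
            self._frames.popleft()

    @property
    def samples(self) -> np.ndarray:
        if not self._frames:
            return np.empty(0)
        return np.concatenate(list(self._frames))

    @property
    def n_frames(self) -> int:
        return len(self._frames)


def update_heat_signatures(
    signatures: Sequence[HeatSignature],
    frame: ThermalFrame,
    shapes: Sequence[np.ndarray | None],
) -> Sequence[HeatSignature]:
    """Append this frame's in-shape temperature samples; evict beyond B frames."""
    for sig, shape in zip(signatures, shapes):
        if shape is not None and shape.any():
            sig.add(frame.values[shape])
    return signatures


def heat_costs(
    cur_samples: Sequence[np.ndarray], signatures: Sequence[HeatSignature]
) -> np.ndarray:
    """KS cost matrix: entry (i, j) compares signature i to current shape j.

    Empty current shapes get a sentinel cost above the KS upper bound of 1.
    """
    m = len(signatures)
    costs = np.full((m, m), KS_SENTINEL)
    for i, sig in enumerate(signatures):
        ref = sig.samples
        if ref.size == 0:
            raise ValueError(f"heat signature for mouse {sig.mouse_id} is empty")
        for j, cur in enumerate(cur_samples):
            if cur is None or len(cur) == 0:
                continue
            costs[i, j] = stats.ks_2samp(ref, cur).statistic
    return costs


def heat_assign(
    cur_samples: Sequence[np.ndarray], signatures: Sequence[HeatSignature]
) -> np.ndarray:
    """Identity correction by KS matching of heat signatures to current shapes.

    cost(i, j) = two-sample KS statistic between signature i's buffered
    samples and shape j's current samples; a greedy global-min assignment on
    this matrix gives the corrected permutation.
    """
    return greedy_assign(heat_costs(cur_samples, signatures))


@dataclass
class MatchingConfig:
    buffer_frames: int = 9
    alpha: float = 0.01
    min_shapes: int = 100
    refit_every: int = 100
    policy: str = "combined"  # "combined" or "distance"
    # a heat permutation that disagrees with the distance one is adopted only
    # when its total KS cost undercuts the distance permutation's by this
    # margin; ambiguous (mixed-shape) frames keep the distance assignment
    heat_margin: float = 0.3


@dataclass
class TrackResult:
    """Per-frame identified poses plus a per-frame strategy/flag log."""

    poses: list  # list over frames: list[MousePose] or (frame_index, status)
    log: pd.DataFrame
    threshold: float

    def valid_frames(self) -> list[int]:
        return [i for i, e in enumerate(self.poses) if not isinstance(e, tuple)]


def track(
    frames: Sequence[ThermalFrame],
    det_cfg: DetectionConfig,
    ws_cfg: WatershedConfig | None = None,
    match_cfg: MatchingConfig | None = None,
    keep_shapes: bool = False,
) -> TrackResult:
    """Run the full tracking pipeline over a video.

    Per frame: foreground segmentation -> blob-count reconciliation ->
    temporal watershed -> greedy distance assignment; when the Hu-moment
    sanity check raises the global misdetection state (and the policy is
    ``combined``), the heat-signature KS assignment overrides the
    distance-based permutation for that frame. Heat signatures and the shape
    statistic are updated only from unflagged frames. Frames consumed by
    re-initialisation or skipped at bootstrap are emitted as
    ``(frame_index, status)`` tuples and excluded from downstream features.
    """
    ws_cfg = ws_cfg or WatershedConfig()
    match_cfg = match_cfg or MatchingConfig()
    m_count = det_cfg.n_mice

    threshold = estimate_threshold(frames, det_cfg)
    shape_stats = ShapeStatistics(
        alpha=match_cfg.alpha,
        min_shapes=match_cfg.min_shapes,
        refit_every=match_cfg.refit_every,
    )
    signatures = [
        HeatSignature(mouse_id=i, buffer_frames=match_cfg.buffer_frames)
        for i in range(m_count)
    ]
    histories: list[deque] = [
        deque(maxlen=max(ws_cfg.history_window, ws_cfg.vote_window + 1))
        for _ in range(m_count)
    ]
    length_hist: list[deque] = [deque(maxlen=ws_cfg.history_window) for _ in range(m_count)]

    prev_poses: list[MousePose] | None = None
    mis_was_active = False
    was_merged = False
    clean_streak = 0
    out: list = []
    log_rows = []

    for frame in frames:
        raw = segment_foreground(frame, threshold)
        cleaned = remove_small_components(raw.mask, det_cfg.min_mouse_area // 2)
        fg = ForegroundMask(mask=cleaned, threshold_used=raw.threshold_used)
        # reconciliation decides the frame status; segmentation keeps the
        # original-resolution mask (dilation is only a counting correction)
        _, status = reconcile_blob_count(fg, det_cfg)
        if status == "reinit":
            out.append((frame.index, "reinit"))
            log_rows.append((frame.index, "reinit", "reinit", np.nan, 0, _count_blobs(fg)))
            continue

        if prev_poses is None:
            try:
                poses = bootstrap_poses(extract_blobs(fg), frame, m_count)
            except TouchingMiceError:
                out.append((frame.index, "skip"))
                log_rows.append((frame.index, "skip", status, np.nan, 0, _count_blobs(fg)))
                continue
            strategy = "bootstrap"
            min_cost = 0.0
            n_flagged = 0
            global_mis_now = False
        else:
            smoothed = [
                float(np.mean(length_hist[i])) if length_hist[i] else prev_poses[i].length
                for i in range(m_count)
            ]
            shapes_poses, _ = em_segment(frame, fg, prev_poses, ws_cfg, smoothed)
            costs = distance_matrix(prev_poses, shapes_poses)
            perm = greedy_assign(costs)
            min_cost = float(costs[np.arange(m_count), perm].min())
            strategy = "distance"

            flags, global_mis = shape_sanity_check(
                shape_stats, [p.hu1 for p in shapes_poses]
            )
            n_flagged = int(flags.sum())
            # consult the heat signatures while the misdetection state is
            # active, once more on the first clean frame after an episode, and
            # when an occlusion (merged-blob) episode ends: identities are
            # genuinely ambiguous inside a merged blob, and separation is the
            # moment a contact-induced swap becomes correctable
            merged_now = status == "merged_for_watershed"
            consult_heat = (
                global_mis
                or (mis_was_active and not global_mis)
                or merged_now
                or (was_merged and not merged_now)
            )
            mis_was_active = global_mis
            was_merged = merged_now
            global_mis_now = global_mis or merged_now
            if consult_heat and match_cfg.policy == "combined" and all(
                s.n_frames > 0 for s in signatures
            ):
                cur_samples = [
                    frame.values[p.shape] if p.shape is not None else np.empty(0)
                    for p in shapes_poses
                ]
                hc = heat_costs(cur_samples, signatures)
                perm_h = greedy_assign(hc)
                idx = np.arange(m_count)
                if np.array_equal(perm_h, perm) or (
                    hc[idx, perm_h].sum() + match_cfg.heat_margin
                    < hc[idx, perm].sum()
                ):
                    perm = perm_h
                    strategy = "heat"

            poses = []
            for i in range(m_count):
                p = shapes_poses[perm[i]]
                p.mouse_id = i
                poses.append(p)

        # orientation vote per identity
        for i in range(m_count):
            poses[i] = correct_orientation(
                list(histories[i]), poses[i], k=ws_cfg.vote_window
            )

        if strategy == "bootstrap":
            clean_streak = match_cfg.buffer_frames
        elif global_mis_now:
            clean_streak = 0
        else:
            clean_streak += 1
        # signatures take samples only from frames well clear of a
        # misdetection episode, so a transient swap cannot contaminate them
        frame_ok = (
            strategy in ("bootstrap", "distance")
            and clean_streak >= match_cfg.buffer_frames
            and all(p.flag == "ok" for p in poses)
        )
        if frame_ok:
            shape_stats.add([p.hu1 for p in poses if p.shape is not None])
            update_heat_signatures(signatures, frame, [p.shape for p in poses])
        for i in range(m_count):
            histories[i].append(poses[i])
            if poses[i].flag == "ok":
                length_hist[i].append(poses[i].length)

        prev_poses = poses
        if not keep_shapes:
            poses = [p for p in poses]
            for p in poses:
                p.shape = None
        out.append(poses)
        log_rows.append((frame.index, strategy, status, min_cost, n_flagged, _count_blobs(fg)))

    log = pd.DataFrame(
        log_rows,
        columns=["frame", "strategy", "status", "min_cost", "n_flagged", "n_blobs"],
    )
    return TrackResult(poses=out, log=log, threshold=threshold)
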