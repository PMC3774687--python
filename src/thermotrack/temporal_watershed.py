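"""EM-iterated seeded watershed splitting touching mice, with pose extraction.

When several mice form one foreground blob, their individual shapes are
recovered by marker-controlled watershed on the negated temperature relief
(warm body interiors become deep basins), seeded from the previous frame's
poses. An EM loop alternates watershed segmentation (E) with moment-based pose
re-estimation (M) until the shapes stabilise. Nose/genitals are placed at the
major-axis extremes; their ordering is kept consistent frame-to-frame and
guarded by a movement-direction voting correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.segmentation import watershed

from .thermal_io import ThermalFrame
from .blob_detection import Blob, ForegroundMask


@dataclass
class WatershedConfig:
    history_window: int = 10  # frames used to smooth body length
    slack: float = 6.0  # px subtracted from the seed span
    max_em_iters: int = 10
    convergence_tol: float = 0.01  # max changed-pixel fraction between EM iters
    vote_window: int = 10  # k, frames for orientation voting
    bg_erosion_iters: int = 2
    relief_sigma: float = 1.0  # Gaussian smoothing of the watershed relief, px
    relief: str = "gradient"  # "gradient" or "neg_temp"

    def __post_init__(self) -> None:
        if min(self.history_window, self.max_em_iters, self.vote_window) <= 0:
            raise ValueError("watershed config values must be positive")
        if self.slack < 0:
            raise ValueError("slack must be non-negative")
        if not (0.0 < self.convergence_tol < 1.0):
            raise ValueError("convergence_tol must lie in (0, 1)")


@dataclass
class MousePose:
    """Keypoint pose of one mouse in one frame.

    ``z`` stacks nose, genitals and centroid into the 6-D position vector used
    for identity matching. ``shape`` holds the body mask while a frame is being
    processed; long-term storage keeps only its summaries (``hu1``, ``area``).
    """

    mouse_id: int
    frame: int
    nose: np.ndarray
    genitals: np.ndarray
    centroid: np.ndarray
    length: float
    shape: np.ndarray | None = None
    hu1: float = 0.0
    area: int = 0
    flag: str = "ok"

    @property
    def z(self) -> np.ndarray:
        return np.concatenate([self.nose, self.genitals, self.centroid]).astype(float)

    @property
    def direction(self) -> np.ndarray:
        """Heading vector from genitals to nose."""
        return self.nose - self.genitals

    def swapped(self) -> "MousePose":
        return MousePose(
            mouse_id=self.mouse_id,
            frame=self.frame,
            nose=self.genitals.copy(),
            genitals=self.nose.copy(),
            centroid=self.centroid,
            length=self.length,
            shape=self.shape,
            hu1=self.hu1,
            area=self.area,
            flag=self.flag,
        )


class TouchingMiceError(Exception):
    """Bootstrap requires one disjoint blob per mouse; the caller should skip."""


def shape_moments(coords: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, float, int]:
    """Centroid, major-axis length, axis direction, first Hu moment and area.

    ``coords`` is an (N, 2) array of (row, col) pixel coordinates. The
    major-axis length is taken from the eigen-decomposition of the covariance
    matrix of the second-order central moments: for a solid ellipse the leading
    eigenvalue is (a/2)^2, so L = 4*sqrt(lambda_1) recovers the full axis 2a.
    hu1 = eta20 + eta02 of the normalised central moments.
    """
    n = coords.shape[0]
    xy = coords[:, ::-1].astype(float)  # (x, y)
    centroid = xy.mean(axis=0)
    d = xy - centroid
    cov = d.T @ d / n
    evals, evecs = np.linalg.eigh(cov)
    lam = max(float(evals[-1]), 0.0)
    axis = evecs[:, -1]
    length = 4.0 * math.sqrt(lam)
    hu1 = float((cov[0, 0] + cov[1, 1]) / n)  # (mu20 + mu02) / mu00^2
    return centroid, length, axis, hu1, n


def _pose_from_coords(
    coords: np.ndarray, mouse_id: int, frame_idx: int, prev: "MousePose | None"
) -> MousePose:
    centroid, length, axis, hu1, area = shape_moments(coords)
    if length < 1e-9:
        # degenerate single-pixel shape
        nose = centroid.copy()
        genitals = centroid.copy()
    else:
        if prev is not None and length < 1e-6:
            axis = prev.direction
        e1 = centroid + 0.5 * length * axis
        e2 = centroid - 0.5 * length * axis
        if prev is not None:
            # orientation minimising summed distance to the previous keypoints
            keep = np.linalg.norm(e1 - prev.nose) + np.linalg.norm(e2 - prev.genitals)
            swap = np.linalg.norm(e2 - prev.nose) + np.linalg.norm(e1 - prev.genitals)
            nose, genitals = (e1, e2) if keep <= swap else (e2, e1)
        else:
            nose, genitals = e1, e2
    return MousePose(
        mouse_id=mouse_id,
        frame=frame_idx,
        nose=nose,
        genitals=genitals,
        centroid=centroid,
        length=length,
        hu1=hu1,
        area=area,
    )


def bootstrap_poses(blobs: Sequence[Blob], frame: ThermalFrame, n_mice: int) -> list[MousePose]:
    """Initial poses from disjoint blobs (first trackable frame).

    Requires exactly one blob per mouse; otherwise raises
    :class:`TouchingMiceError` and the caller advances to the next frame.
    The nose/genitals assignment is provisional (arbitrary but recorded); the
    orientation vote corrects it once the mouse moves.
    """
    if len(blobs) != n_mice:
        raise TouchingMiceError(f"expected {n_mice} disjoint blobs, found {len(blobs)}")
    poses = []
    for i, blob in enumerate(blobs):
        pose = _pose_from_coords(blob.pixels, mouse_id=i, frame_idx=frame.index, prev=None)
        shape = np.zeros(frame.shape, dtype=bool)
        shape[blob.pixels[:, 0], blob.pixels[:, 1]] = True
        pose.shape = shape
        poses.append(pose)
    return poses


def build_seeds(
    prev_poses: Sequence[MousePose],
    foreground: np.ndarray,
    cfg: WatershedConfig,
    smoothed_lengths: Sequence[float] | None = None,
) -> np.ndarray:
    """Seed/marker image: 0 unknown, 1..M mouse seeds, M+1 background seed.

    Each mouse seed is three collinear points (nose, centroid and genitals
    positions taken from the previous pose) with the end points pulled in so
    the seed spans the history-smoothed body length minus the slack constant:
    the shrunken seed tolerates between-frame displacement without leaking
    into a neighbour. Points falling outside the current foreground are
    snapped to the nearest foreground pixel; conflicting claims go to the
    mouse with the nearer previous centroid. The background seed is the
    eroded complement of the foreground.
    """
    h, w = foreground.shape
    m_count = len(prev_poses)
    seeds = np.zeros((h, w), dtype=np.int32)
    owner_dist = np.full((h, w), np.inf)

    snap = None
    if foreground.any():
        # nearest-foreground lookup for seed points that fell on background
        _, snap = ndimage.distance_transform_edt(~foreground, return_indices=True)

    for m, pose in enumerate(prev_poses):
        span = (
            smoothed_lengths[m] if smoothed_lengths is not None else pose.length
        ) - cfg.slack
        span = max(span, 0.0)
        d = pose.direction
        nrm = np.linalg.norm(d)
        d_hat = d / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
        points = [
            pose.centroid + 0.5 * span * d_hat,
            pose.centroid,
            pose.centroid - 0.5 * span * d_hat,
        ]
        for p in points:
            x = int(round(min(max(p[0], 0), w - 1)))
            y = int(round(min(max(p[1], 0), h - 1)))
            if snap is not None and not foreground[y, x]:
                y, x = int(snap[0][y, x]), int(snap[1][y, x])
            dist = float(np.hypot(x - pose.centroid[0], y - pose.centroid[1]))
            if dist < owner_dist[y, x]:
                owner_dist[y, x] = dist
                seeds[y, x] = m + 1

    bg = ~foreground
    if cfg.bg_erosion_iters > 0:
        eroded = ndimage.binary_erosion(
            bg, structure=np.ones((3, 3), bool), iterations=cfg.bg_erosion_iters
        )
        if eroded.any():
            bg = eroded
    seeds[bg & (seeds == 0)] = m_count + 1
    return seeds


def _assign_orphans(labels: np.ndarray, foreground: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Give seedless foreground components to the mouse with the nearest centroid."""
    orphan = foreground & (labels == 0)
    if not orphan.any():
        return labels
    comp = measure.label(orphan, connectivity=2)
    for region in measure.regionprops(comp):
        cy, cx = region.centroid
        m = int(np.argmin(np.linalg.norm(centroids - np.array([cx, cy]), axis=1)))
        labels[comp == region.label] = m + 1
    return labels


def em_segment(
    frame: ThermalFrame,
    foreground: ForegroundMask,
    prev_poses: Sequence[MousePose],
    cfg: WatershedConfig,
    smoothed_lengths: Sequence[float] | None = None,
) -> tuple[list[MousePose], int]:
    """Split the foreground into per-mouse shapes by EM-iterated watershed.

    E-step: marker-controlled watershed on the negated temperature relief,
    restricted to the foreground, seeded from the current pose estimates
    (previous frame's poses on the first iteration). M-step: per-shape moments
    give centroid, length and axis end points, oriented towards the previous
    frame's nose/genitals. Iterates until the changed-pixel fraction drops
    below ``convergence_tol`` or ``max_em_iters`` is reached.

    Returns the per-mouse poses (shapes forming an exact partition of the
    foreground) and the number of EM iterations run. A mouse whose watershed
    shape comes out empty keeps its previous pose with ``flag='mistrack'``.
    """
    fg = foreground.mask
    m_count = len(prev_poses)
    sigma = max(cfg.relief_sigma, 1e-6)
    if cfg.relief == "gradient":
        # temperature-edge relief: the contact line between two bodies (a
        # temperature step or dip) becomes a ridge, so neither basin can
        # swallow a differently-warm neighbour
        relief = ndimage.gaussian_gradient_magnitude(frame.values, sigma)
    else:
        # negated temperature: warm interiors are deep basins
        relief = ndimage.gaussian_filter(-frame.values, sigma)
    cur_poses = list(prev_poses)
    cur_lengths = smoothed_lengths
    prev_labels = None
    n_iters = 0
    fg_area = int(fg.sum())
    for it in range(cfg.max_em_iters):
        n_iters = it + 1
        seeds = build_seeds(cur_poses, fg, cfg, smoothed_lengths=cur_lengths)
        mouse_markers = np.where(seeds <= m_count, seeds, 0)
        labels = watershed(relief, markers=mouse_markers, mask=fg)
        centroids = np.array([p.centroid for p in cur_poses])
        labels = _assign_orphans(labels, fg, centroids)

        new_poses: list[MousePose] = []
        for m in range(m_count):
            coords = np.argwhere(labels == m + 1)
            if coords.shape[0] == 0:
                lost = MousePose(
                    mouse_id=prev_poses[m].mouse_id,
                    frame=frame.index,
                    nose=prev_poses[m].nose.copy(),
                    genitals=prev_poses[m].genitals.copy(),
                    centroid=prev_poses[m].centroid.copy(),
                    length=prev_poses[m].length,
                    flag="mistrack",
                )
                new_poses.append(lost)
                continue
            pose = _pose_from_coords(
                coords, mouse_id=prev_poses[m].mouse_id, frame_idx=frame.index,
                prev=prev_poses[m],
            )
            pose.shape = labels == m + 1
            new_poses.append(pose)
        cur_poses = new_poses
        cur_lengths = None  # later iterations use current length estimates

        if prev_labels is not None and fg_area > 0:
            changed = np.count_nonzero(labels != prev_labels) / fg_area
            if changed < cfg.convergence_tol:
                prev_labels = labels
                break
        prev_labels = labels
    return cur_poses, n_iters


def correct_orientation(
    pose_history: Sequence[MousePose], current_pose: MousePose, k: int | None = None
) -> MousePose:
    """Movement-vote nose/genitals correction.

    Over the last ``k`` frames (history followed by the current pose) each
    frame contributes sign(<movement vector, heading vector>): movement is the
    centroid displacement from the previous frame, heading runs genitals to
    nose. Stationary frames contribute 0. A negative total vote means the
    animal has been moving backwards relative to its assigned heading for most
    of the window, so nose and genitals are swapped.
    """
    seq = list(pose_history) + [current_pose]
    if len(seq) < 2:
        return current_pose
    if k is None:
        k = len(seq) - 1
    vote = 0
    pairs = list(zip(seq[:-1], seq[1:]))[-k:]
    for prev, cur in pairs:
        movement = cur.centroid - prev.centroid
        dot = float(np.dot(movement, cur.direction))
        if abs(dot) > 1e-12:
            vote += 1 if dot > 0 else -1
    if vote < 0:
        return current_pose.swapped()
    return current_pose
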