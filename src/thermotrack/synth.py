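"""Synthetic top-view thermal video with ground truth.

Mice are rendered as warm ellipses (optionally with a thin 1-2 px tail
polyline) at a fixed temperature offset over a noisy cooler background,
following scripted piecewise-linear trajectories. Each scripted segment
declares the ground-truth behaviour label for every ordered mouse pair; the
prebuilt factories in :mod:`thermotrack.scenarios` place the animals so those
labels satisfy the ethogram's distance conventions (0.5 cm for sniffing
contacts, 3 cm for standing together, 10 cm for being alone) at the configured
pixel-per-centimetre scale.

Generation is a pure function of the spec and its seed: the same spec yields
bit-identical frame stacks on every call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .thermal_io import ThermalFrame, DEFAULT_FPS

#: default spatial scale: a 40 cm arena imaged across 160 px
DEFAULT_PX_PER_CM = 4.0


class InfeasibleScriptError(ValueError):
    """The scripted trajectories leave the arena or do not tile the video."""


@dataclass
class MouseSpec:
    """Per-mouse rendering parameters.

    half_axes : (a, b) ellipse half-axes in px (a = half body length).
    temp_offset : body temperature above background mean, in units.
    tail_length : tail polyline length in px (0 disables the tail).
    tail_width : tail thickness in px (1 or 2).
    """

    half_axes: tuple[float, float] = (10.0, 4.0)
    temp_offset: float = 5.0
    tail_length: float = 8.0
    tail_width: int = 1


@dataclass
class MotionPiece:
    """A piecewise-linear trajectory element for one mouse.

    The centroid moves linearly from ``start`` to ``end`` over ``n_frames``
    frames. ``theta`` fixes the heading (radians, 0 = +x); ``None`` makes the
    heading follow the direction of motion (or keep the previous heading while
    stationary); a 2-tuple interpolates linearly between two headings.
    """

    n_frames: int
    start: tuple[float, float]
    end: tuple[float, float] | None = None
    theta: float | tuple[float, float] | None = None

    def pose_at(self, k: int, prev_theta: float) -> tuple[np.ndarray, float]:
        """Centroid and heading at local frame k in [0, n_frames)."""
        end = self.start if self.end is None else self.end
        u = 0.0 if self.n_frames <= 1 else k / (self.n_frames - 1)
        c = (1 - u) * np.asarray(self.start, float) + u * np.asarray(end, float)
        if isinstance(self.theta, tuple):
            th = (1 - u) * self.theta[0] + u * self.theta[1]
        elif self.theta is not None:
            th = float(self.theta)
        else:
            d = np.asarray(end, float) - np.asarray(self.start, float)
            th = math.atan2(d[1], d[0]) if np.hypot(*d) > 1e-9 else prev_theta
        return c, th


@dataclass
class Segment:
    """A labelled span of frames: [start, end) with one label per ordered pair."""

    start: int
    end: int
    labels: dict[tuple[int, int], str] = field(default_factory=dict)


@dataclass
class ScenarioSpec:
    """Full description of a synthetic recording."""

    arena: tuple[int, int] = (160, 160)  # (height, width) px
    mice: list[MouseSpec] = field(default_factory=lambda: [MouseSpec()])
    motions: list[list[MotionPiece]] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    bg_mean: float = 20.0
    noise_sd: float = 0.5
    seed: int = 0
    fps: float = DEFAULT_FPS
    px_per_cm: float = DEFAULT_PX_PER_CM

    @property
    def n_mice(self) -> int:
        return len(self.mice)

    @property
    def n_frames(self) -> int:
        if not self.motions:
            return 0
        return sum(p.n_frames for p in self.motions[0])

    def validate(self) -> None:
        if self.n_mice < 1:
            raise InfeasibleScriptError("at least one mouse required")
        if len(self.motions) != self.n_mice:
            raise InfeasibleScriptError("one motion script required per mouse")
        n = self.n_frames
        for i, pieces in enumerate(self.motions):
            if sum(p.n_frames for p in pieces) != n:
                raise InfeasibleScriptError(f"mouse {i} script does not span {n} frames")
        for m in self.mice:
            if m.temp_offset <= self.noise_sd:
                raise InfeasibleScriptError("temperature offset must exceed noise sd")
        # segments must tile [0, n) without overlap
        segs = sorted(self.segments, key=lambda s: s.start)
        cursor = 0
        for s in segs:
            if s.start != cursor or s.end <= s.start:
                raise InfeasibleScriptError("segments must tile the video without overlap")
            cursor = s.end
        if segs and cursor != n:
            raise InfeasibleScriptError("segments must cover the whole video")


def spec_from_dict(data: dict) -> ScenarioSpec:
    """Build a ScenarioSpec from plain key-value data (e.g. parsed YAML).

    Expected layout::

        arena: [160, 160]
        bg_mean: 20.0
        noise_sd: 0.5
        seed: 0
        mice:
          - {half_axes: [10, 4], temp_offset: 5.0, tail_length: 8}
        motions:            # one list of pieces per mouse
          - - {n_frames: 100, start: [30, 80], end: [120, 80]}
        segments:
          - {start: 0, end: 100, labels: {"0,1": WalkAlone, "1,0": WalkAlone}}
    """
    mice = [MouseSpec(**{**m, "half_axes": tuple(m.get("half_axes", (10.0, 4.0)))})
            for m in data.get("mice", [{}])]
    motions = []
    for pieces in data.get("motions", []):
        motions.append(
            [
                MotionPiece(
                    n_frames=int(p["n_frames"]),
                    start=tuple(p["start"]),
                    end=tuple(p["end"]) if p.get("end") is not None else None,
                    theta=tuple(p["theta"]) if isinstance(p.get("theta"), (list, tuple))
                    else p.get("theta"),
                )
                for p in pieces
            ]
        )
    segments = []
    for s in data.get("segments", []):
        labels = {
            tuple(int(x) for x in key.split(",")): str(lab)
            for key, lab in (s.get("labels") or {}).items()
        }
        segments.append(Segment(start=int(s["start"]), end=int(s["end"]), labels=labels))
    kwargs = {
        k: data[k]
        for k in ("bg_mean", "noise_sd", "seed", "fps", "px_per_cm")
        if k in data
    }
    if "arena" in data:
        kwargs["arena"] = tuple(data["arena"])
    return ScenarioSpec(mice=mice, motions=motions, segments=segments, **kwargs)


def load_scenario(path) -> ScenarioSpec:
    """Read a scenario spec from a key-value (YAML) config file."""
    import yaml

    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


@dataclass
class TruePose:
    """Analytic ground-truth pose of one mouse in one frame."""

    centroid: np.ndarray
    theta: float
    half_axes: tuple[float, float]

    @property
    def nose(self) -> np.ndarray:
        a = self.half_axes[0]
        return self.centroid + a * np.array([math.cos(self.theta), math.sin(self.theta)])

    @property
    def genitals(self) -> np.ndarray:
        a = self.half_axes[0]
        return self.centroid - a * np.array([math.cos(self.theta), math.sin(self.theta)])

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterise the body ellipse (tail excluded) on a grid of given shape."""
        return _ellipse_mask(shape, self.centroid, self.theta, self.half_axes)


@dataclass
class GroundTruth:
    """Per-frame true poses and per-frame ordered-pair behaviour labels."""

    poses: list[list[TruePose]]
    pair_labels: dict[tuple[int, int, int], str]  # (frame, ref, target) -> label
    spec: ScenarioSpec

    def label_track(self, ref: int, target: int) -> list[str]:
        n = len(self.poses)
        return [self.pair_labels.get((t, ref, target), "unknown") for t in range(n)]

    def centroid_track(self, mouse: int) -> np.ndarray:
        return np.array([self.poses[t][mouse].centroid for t in range(len(self.poses))])


def _ellipse_mask(
    shape: tuple[int, int],
    centroid: np.ndarray,
    theta: float,
    half_axes: tuple[float, float],
) -> np.ndarray:
    h, w = shape
    a, b = half_axes
    cx, cy = float(centroid[0]), float(centroid[1])
    x0 = max(0, int(cx - a - 2))
    x1 = min(w, int(cx + a + 3))
    y0 = max(0, int(cy - a - 2))
    y1 = min(h, int(cy + a + 3))
    mask = np.zeros(shape, dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    mask[y0:y1, x0:x1] = u * u + v * v <= 1.0
    return mask


def _tail_mask(
    shape: tuple[int, int],
    pose: TruePose,
    length: float,
    width: int,
) -> np.ndarray:
    """Thin tail polyline extending backwards from the genitals tip."""
    mask = np.zeros(shape, dtype=bool)
    if length <= 0:
        return mask
    h, w = shape
    ct, st = math.cos(pose.theta), math.sin(pose.theta)
    base = pose.genitals
    n_samples = max(2, int(2 * length))
    for s in np.linspace(0.0, length, n_samples):
        # slight sinusoidal wiggle so the tail is not a perfect SE match
        wig = 0.8 * math.sin(s / max(length, 1e-9) * math.pi)
        px = base[0] - s * ct - wig * st
        py = base[1] - s * st + wig * ct
        x, y = int(round(px)), int(round(py))
        for ox in range(width):
            for oy in range(width):
                xi, yi = x + ox, y + oy
                if 0 <= xi < w and 0 <= yi < h:
                    mask[yi, xi] = True
    return mask


def scripted_poses(spec: ScenarioSpec) -> list[list[TruePose]]:
    """Evaluate the motion scripts into per-frame analytic poses."""
    n = spec.n_frames
    poses: list[list[TruePose]] = [[] for _ in range(n)]
    for m, pieces in enumerate(spec.motions):
        t = 0
        prev_theta = 0.0
        for piece in pieces:
            for k in range(piece.n_frames):
                c, th = piece.pose_at(k, prev_theta)
                poses[t].append(TruePose(c, th, spec.mice[m].half_axes))
                prev_theta = th
                t += 1
    return poses


def generate_scenario(spec: ScenarioSpec) -> tuple[list[ThermalFrame], GroundTruth]:
    """Render a scripted scenario into thermal frames plus ground truth.

    Deterministic given ``spec.seed``. Bodies are ellipses at
    ``bg_mean + temp_offset`` with additive Gaussian pixel noise everywhere;
    where two bodies overlap the warmer one wins. Raises
    :class:`InfeasibleScriptError` at build time if a body leaves the arena or
    the scripts/segments do not tile the video.
    """
    spec.validate()
    h, w = spec.arena
    n = spec.n_frames
    poses = scripted_poses(spec)

    # feasibility: bodies (incl. tails) must stay inside the arena
    for t in range(n):
        for m, pose in enumerate(poses[t]):
            a = spec.mice[m].half_axes[0]
            reach = a + spec.mice[m].tail_length + 2
            cx, cy = pose.centroid
            if not (reach <= cx <= w - 1 - reach and reach <= cy <= h - 1 - reach):
                if not (a + 1 <= cx <= w - 2 - a and a + 1 <= cy <= h - 2 - a):
                    raise InfeasibleScriptError(
                        f"mouse {m} leaves the arena at frame {t} (centroid {cx:.1f},{cy:.1f})"
                    )

    rng = np.random.default_rng(spec.seed)
    period = 1.0 / spec.fps
    frames: list[ThermalFrame] = []
    for t in range(n):
        values = spec.bg_mean + rng.normal(0.0, spec.noise_sd, size=(h, w))
        body_temp = np.zeros((h, w))
        for m, pose in enumerate(poses[t]):
            ms = spec.mice[m]
            body = pose.mask((h, w))
            tail = _tail_mask((h, w), pose, ms.tail_length, ms.tail_width)
            warm = body | tail
            body_temp[warm] = np.maximum(body_temp[warm], ms.temp_offset)
        values = values + body_temp
        frames.append(ThermalFrame(values, index=t, period=period))

    pair_labels: dict[tuple[int, int, int], str] = {}
    for seg in spec.segments:
        for t in range(seg.start, seg.end):
            for (i, j), lab in seg.labels.items():
                pair_labels[(t, i, j)] = lab
    return frames, GroundTruth(poses=poses, pair_labels=pair_labels, spec=spec)
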