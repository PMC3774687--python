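"""Prebuilt synthetic scenarios exercising each pipeline stage.

Geometry follows the default spatial scale of 4 px/cm (a 40 cm arena across
160 px), so the ethogram's distance conventions translate to 2 px (0.5 cm
sniffing contact), 12 px (3 cm standing together) and 40 px (10 cm alone).
Bodies are 20 x 8 px ellipses (5 x 2 cm, an adult mouse seen from above) with
8 px tails, 5-6.5 units warmer than a background with 0.5 units of pixel
noise — a conservative stand-in for the >10 degC contrast a thermal camera
sees between mouse fur and bedding.
"""

from __future__ import annotations

import math

import numpy as np

from .synth import MouseSpec, MotionPiece, ScenarioSpec, Segment

BODY = (10.0, 4.0)  # half-axes, px
TAIL = 8.0


def _mouse(offset: float) -> MouseSpec:
    return MouseSpec(half_axes=BODY, temp_offset=offset, tail_length=TAIL)


def disjoint_scenario(n_mice: int = 3, n_frames: int = 300, seed: int = 0) -> ScenarioSpec:
    """Mice patrolling separate horizontal lanes; never within touching range."""
    lanes = np.linspace(36, 124, n_mice)
    motions = []
    half = n_frames // 2
    for m in range(n_mice):
        y = float(lanes[m])
        x0, x1 = (40.0, 120.0) if m % 2 == 0 else (120.0, 40.0)
        motions.append(
            [
                MotionPiece(half, (x0, y), (x1, y)),
                MotionPiece(n_frames - half, (x1, y), (x0, y)),
            ]
        )
    mice = [_mouse(5.0 + 0.6 * m) for m in range(n_mice)]
    labels = {
        (i, j): "WalkAlone" for i in range(n_mice) for j in range(n_mice) if i != j
    }
    return ScenarioSpec(
        mice=mice,
        motions=motions,
        segments=[Segment(0, n_frames, labels)],
        seed=seed,
    )


def touching_pair_scenario(n_frames: int = 200, seed: int = 0) -> ScenarioSpec:
    """Two mice converge (disjoint warm-up) then walk side by side in contact."""
    n_approach = 60
    n_rest = n_frames - n_approach
    motions = [
        [
            MotionPiece(n_approach, (40.0, 60.0), (78.0, 76.0)),
            MotionPiece(n_rest, (78.0, 76.0), (120.0, 76.0), theta=0.0),
        ],
        [
            MotionPiece(n_approach, (40.0, 100.0), (78.0, 84.0)),
            MotionPiece(n_rest, (78.0, 84.0), (120.0, 84.0), theta=0.0),
        ],
    ]
    labels = {(0, 1): "StandTogether", (1, 0): "StandTogether"}
    walk = {(0, 1): "WalkAlone", (1, 0): "WalkAlone"}
    return ScenarioSpec(
        mice=[_mouse(5.0), _mouse(6.5)],
        motions=motions,
        segments=[Segment(0, n_approach, walk), Segment(n_approach, n_frames, labels)],
        seed=seed,
    )


def crossing_paths_scenario(n_mice: int = 2, n_frames: int = 300, seed: int = 0) -> ScenarioSpec:
    """Perpendicular paths crossing near the arena centre with a brief contact.

    Mouse 0 walks west-to-east along y = 80; mouse 1 walks north-to-south
    along x = 80, phased so the bodies brush past each other around frame
    ~110 and form a single blob for a short episode. An optional third mouse
    patrols a southern lane and stays clear of the encounter.
    """
    motions = [
        [MotionPiece(n_frames, (28.0, 80.0), (132.0, 80.0))],
        [MotionPiece(n_frames, (90.0, 24.0), (90.0, 132.0))],
    ]
    mice = [_mouse(5.0), _mouse(6.5)]
    if n_mice >= 3:
        motions.append([MotionPiece(n_frames, (30.0, 136.0), (120.0, 136.0))])
        mice.append(_mouse(5.75))
    if n_mice not in (2, 3):
        raise ValueError("crossing_paths_scenario supports 2 or 3 mice")
    labels = {(i, j): "WalkAlone" for i in range(n_mice) for j in range(n_mice) if i != j}
    return ScenarioSpec(
        mice=mice,
        motions=motions,
        segments=[Segment(0, n_frames, labels)],
        seed=seed,
    )


def four_class_cycle(n_cycles: int = 12, seed: int = 0) -> ScenarioSpec:
    """M=2 scripted ethogram cycling StandAlone / WalkAlone / Nose2Nose / StandTogether.

    Each 450-frame cycle: the mice stand at opposite ends of the arena
    (96 px apart, 24 cm > 10 cm: StandAlone), walk towards each other
    (WalkAlone), hold a nose-to-nose contact with a 1 px nose gap (< 0.5 cm:
    Nose2Nose), sidestep into a side-by-side anti-parallel rest 11.3 px apart
    (< 3 cm, heads pointing away: StandTogether) and walk back out
    (WalkAlone). At 30 fps, 12 cycles give 5400 frames (3 minutes of video)
    with every class present in every third of the recording.
    """
    home0, home1 = (32.0, 80.0), (128.0, 80.0)
    nose0, nose1 = (69.5, 80.0), (90.5, 80.0)  # noses 1 px apart
    side0, side1 = (76.0, 76.0), (84.0, 84.0)  # centroids 11.3 px apart
    pieces0, pieces1, segments = [], [], []
    both = lambda lab: {(0, 1): lab, (1, 0): lab}
    t = 0
    for _ in range(n_cycles):
        for n_f, p0, p1, lab in [
            (90, MotionPiece(90, home0, theta=0.0), MotionPiece(90, home1, theta=math.pi), "StandAlone"),
            (60, MotionPiece(60, home0, nose0, theta=0.0), MotionPiece(60, home1, nose1, theta=math.pi), "WalkAlone"),
            (90, MotionPiece(90, nose0, theta=0.0), MotionPiece(90, nose1, theta=math.pi), "Nose2Nose"),
            (30, MotionPiece(30, nose0, side0, theta=0.0), MotionPiece(30, nose1, side1, theta=math.pi), "WalkAlone"),
            (90, MotionPiece(90, side0, theta=0.0), MotionPiece(90, side1, theta=math.pi), "StandTogether"),
            (90, MotionPiece(90, side0, home0), MotionPiece(90, side1, home1), "WalkAlone"),
        ]:
            pieces0.append(p0)
            pieces1.append(p1)
            segments.append(Segment(t, t + n_f, both(lab)))
            t += n_f
    return ScenarioSpec(
        mice=[_mouse(5.0), _mouse(6.0)],
        motions=[pieces0, pieces1],
        segments=segments,
        seed=seed,
    )


# --------------------------------------------------------------------------
# synthetic per-pair feature sequences (no rendering), for classifier studies
# --------------------------------------------------------------------------

#: plausible per-class means of the 13 features, in px / px^2 units, matching
#: the geometry of the rendered scenarios above
CLASS_FEATURE_MEANS = {
    "Nose2Nose": [2, 12, 22, 40, 20, 0.23, 250, 1, 1, 0.3, 0.3, 1, 1],
    "Nose2Genitals": [2, 10, 2, 22, 18, 0.23, 250, 1, 1, 0.3, 0.3, 1, 1],
    "StandTogether": [14, 12, 16, 14, 11, 0.23, 250, 1, 1, 0.3, 0.3, 1, 1],
    "StandAlone": [96, 90, 92, 96, 90, 0.23, 250, 1, 1, 0.3, 0.3, 1, 1],
    "WalkAlone": [60, 55, 57, 60, 55, 0.20, 240, 9, 9, 3, 0.6, 3, 9],
    "Following": [25, 15, 8, 25, 15, 0.20, 240, 9, 9, 3, 0.6, 3, 9],
    "Nose2Body": [8, 2, 8, 20, 15, 0.23, 250, 1, 1, 0.3, 0.3, 1, 1],
    "Above": [5, 3, 5, 6, 4, 0.30, 180, 2, 2, 0.8, 0.8, 2, 2],
}


def synthetic_feature_sequence(
    labels: list[str], noise_sd: float = 2.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-frame 13-feature rows: class means plus i.i.d. Gaussian noise."""
    rng = rng or np.random.default_rng(0)
    rows = np.stack([CLASS_FEATURE_MEANS[l] for l in labels]).astype(float)
    return np.abs(rows + rng.normal(0.0, noise_sd, size=rows.shape))


def segment_labels(segment_classes: list[str], segment_length: int) -> list[str]:
    """Constant-length labelled segments concatenated into one track."""
    out: list[str] = []
    for c in segment_classes:
        out.extend([c] * segment_length)
    return out
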