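"""Frame-by-frame agreement, duration differences and contiguous k-fold CV.

Accuracy = (TP+TN)/(TP+TN+FP+FN) and Precision = TP/(TP+FP), computed both on
the full eight-class vocabulary and after grouping into social vs non-social
meta-classes. Duration differences compare the total time assigned to each
meta-class by two label tracks. Cross-validation folds are contiguous blocks
(frame ordering intact), avoiding temporal leakage between train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combine import BEHAVIOUR_CLASSES, SOCIAL_CLASSES, NONSOCIAL_CLASSES

UNKNOWN = "unknown"


def social_map(standtogether_social: bool = False) -> dict[str, str]:
    """Class -> meta-class map; StandTogether's side is configurable."""
    out = {c: "social" for c in SOCIAL_CLASSES}
    out.update({c: "nonsocial" for c in NONSOCIAL_CLASSES})
    out["StandTogether"] = "social" if standtogether_social else "nonsocial"
    return out


@dataclass
class AgreementReport:
    acc_full: float  # % frames with identical class
    acc_soc_vs_nsoc: float  # % frames agreeing after social/non-social grouping
    prec_soc: float
    prec_nsoc: float
    confusion: pd.DataFrame  # 8x8, rows = truth, cols = prediction
    n_frames: int


@dataclass
class DurationReport:
    social_diff_s: float
    nonsocial_diff_s: float
    per_class_diff_s: dict[str, float]
    social_diff_pct: float  # % of total video time
    nonsocial_diff_pct: float
    video_length_s: float


def frame_agreement(
    pred, truth, meta: dict[str, str] | None = None
) -> AgreementReport:
    """Frame-by-frame agreement between a predicted and a reference track.

    ``unknown`` frames in either track are excluded pairwise. The meta-class
    metrics take "social" as the positive class for prec_soc and "nonsocial"
    as positive for prec_nsoc.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("tracks must have equal length")
    keep = (pred != UNKNOWN) & (truth != UNKNOWN)
    p, g = pred[keep], truth[keep]
    n = len(p)
    if n == 0:
        raise ValueError("no jointly labelled frames")
    meta = meta or social_map()
    acc_full = 100.0 * float(np.mean(p == g))

    pm = np.array([meta[x] for x in p])
    gm = np.array([meta[x] for x in g])
    acc_meta = 100.0 * float(np.mean(pm == gm))

    def precision(positive: str) -> float:
        predicted_pos = pm == positive
        if predicted_pos.sum() == 0:
            return 100.0
        return 100.0 * float(np.mean(gm[predicted_pos] == positive))

    conf = pd.DataFrame(
        0, index=BEHAVIOUR_CLASSES, columns=BEHAVIOUR_CLASSES, dtype=int
    )
    for gt, pr in zip(g, p):
        conf.loc[gt, pr] += 1

    return AgreementReport(
        acc_full=acc_full,
        acc_soc_vs_nsoc=acc_meta,
        prec_soc=precision("social"),
        prec_nsoc=precision("nonsocial"),
        confusion=conf,
        n_frames=n,
    )


def duration_difference(
    pred, truth, period: float, meta: dict[str, str] | None = None
) -> DurationReport:
    """Absolute total-duration differences, grouped social vs non-social."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("tracks must have equal length")
    keep = (pred != UNKNOWN) & (truth != UNKNOWN)
    p, g = pred[keep], truth[keep]
    meta = meta or social_map()
    video_len = len(p) * period

    def group_seconds(track, group):
        return float(sum(meta[x] == group for x in track)) * period

    soc = abs(group_seconds(p, "social") - group_seconds(g, "social"))
    nsoc = abs(group_seconds(p, "nonsocial") - group_seconds(g, "nonsocial"))
    per_class = {
        c: abs(float(np.sum(p == c)) - float(np.sum(g == c))) * period
        for c in BEHAVIOUR_CLASSES
    }
    pct = (lambda s: 100.0 * s / video_len if video_len > 0 else 0.0)
    return DurationReport(
        social_diff_s=soc,
        nonsocial_diff_s=nsoc,
        per_class_diff_s=per_class,
        social_diff_pct=pct(soc),
        nonsocial_diff_pct=pct(nsoc),
        video_length_s=video_len,
    )


def contiguous_kfold(n_frames: int, k: int = 3) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous train/test index partitions (no shuffling).

    Returns k pairs ``(train_idx, test_idx)``; test blocks are contiguous,
    disjoint, exhaustive, with sizes differing by at most 1.
    """
    if k > n_frames:
        raise ValueError("more folds than frames")
    bounds = np.linspace(0, n_frames, k + 1).round().astype(int)
    out = []
    all_idx = np.arange(n_frames)
    for f in range(k):
        test = all_idx[bounds[f] : bounds[f + 1]]
        train = np.concatenate([all_idx[: bounds[f]], all_idx[bounds[f + 1] :]])
        out.append((train, test))
    return out


def identity_agreement(track_result, ground_truth) -> tuple[float, int]:
    """Fraction of frames with correct identities, and intervention count.

    The intervention count is the number of maximal episodes of disagreement
    with the canonical correspondence: each episode is one point where a
    human curator would have to step in and restore the identities, the
    quantity the manual-correction workflow measures.

    Each valid frame's true poses are matched one-to-one to the estimated
    poses by greedy minimum-distance assignment on centroids (a bijection, so
    deep occlusions cannot collapse two true mice onto one estimate). The
    correspondence established on the first valid frame defines the canonical
    naming (tracker identities are assigned in arbitrary blob order at
    bootstrap); a frame agrees when its correspondence equals the canonical
    one.
    """
    from .matching import greedy_assign

    agree = 0
    total = 0
    interventions = 0
    base_map: tuple | None = None
    prev_ok = True
    for entry in track_result.poses:
        if isinstance(entry, tuple):
            continue
        t = entry[0].frame
        true_poses = ground_truth.poses[t]
        est_centroids = np.stack([p.centroid for p in entry])
        true_centroids = np.stack([tp.centroid for tp in true_poses])
        costs = np.linalg.norm(
            true_centroids[:, None, :] - est_centroids[None, :, :], axis=2
        )
        perm = greedy_assign(costs)
        mapping = tuple(entry[j].mouse_id for j in perm)
        if base_map is None:
            base_map = mapping
        total += 1
        ok = mapping == base_map
        if ok:
            agree += 1
        elif prev_ok:
            interventions += 1
        prev_ok = ok
    if total == 0:
        raise ValueError("no valid frames to evaluate")
    return agree / total, interventions
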