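"""Temporal Random Forest: per-offset tree ensembles voting across a window.

For every temporal offset delta in [-w, +w] an ensemble of N unpruned,
information-gain decision trees is trained on (features at frame t+delta,
label at frame t): each offset's trees see the data from a shifted
perspective, so the pooled (2w+1)*N votes for a frame exploit past, present
and future evidence about the central frame's behaviour. Each tree draws its
own random feature subspace of size d (and, by default, a bootstrap resample
of the training rows). The per-frame prediction is the mode of all votes,
which doubles as a temporal regulariser suppressing single-frame label
flicker.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES
from .combine import DEFAULT_PRIORITIES

UNKNOWN = "unknown"


@dataclass
class ForestConfig:
    n_trees: int = 5  # N trees per offset
    window_radius: int = 15  # w
    subspace_dim: int = 4  # d, ~sqrt(13)
    bootstrap: bool = True
    per_split_subspace: bool = False
    balanced_bootstrap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.window_radius < 0:
            raise ValueError("need n_trees >= 1 and window_radius >= 0")
        if not (1 <= self.subspace_dim <= len(FEATURE_NAMES)):
            raise ValueError("subspace_dim must lie in [1, 13]")


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[FEATURE_NAMES].to_numpy(dtype=float)
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"feature matrix must have {len(FEATURE_NAMES)} columns")
    return arr


@dataclass
class TemporalForest:
    config: ForestConfig
    classes: list[str]
    # trees[delta_index] = list of (tree, subspace indices)
    trees: list[list[tuple[DecisionTreeClassifier, np.ndarray]]] = field(default_factory=list)
    priorities: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PRIORITIES))

    # ------------------------------------------------------------------ train
    @classmethod
    def fit(
        cls,
        feature_sequences: Sequence,
        label_sequences: Sequence[Sequence[str]],
        cfg: ForestConfig | None = None,
    ) -> "TemporalForest":
        """Train on per-pair ordered feature tables and aligned label tracks.

        Frames labelled ``unknown`` never serve as training centres, but their
        features may still be seen through a neighbour's offset window.
        Offsets reaching past a sequence's ends are clamped to the first/last
        frame. Deterministic given ``cfg.seed``. A single-class training set
        yields a valid constant predictor (degenerate forest).
        """
        cfg = cfg or ForestConfig()
        mats = [_as_matrix(f) for f in feature_sequences]
        labs = [np.asarray(l, dtype=object) for l in label_sequences]
        for x, y in zip(mats, labs):
            if len(x) != len(y):
                raise ValueError("features and labels must align per sequence")
        classes = sorted({str(l) for y in labs for l in y if l != UNKNOWN})
        if not classes:
            raise ValueError("no labelled frames to train on")
        if len(classes) < 2:
            import warnings

            warnings.warn("single-class training set: forest degenerates to a constant predictor")

        rng = np.random.default_rng(cfg.seed)
        n_feat = len(FEATURE_NAMES)
        offsets = range(-cfg.window_radius, cfg.window_radius + 1)
        all_trees = []
        for delta in offsets:
            xs, ys = [], []
            for x, y in zip(mats, labs):
                t_idx = np.arange(len(y))
                keep = y != UNKNOWN
                src = np.clip(t_idx + delta, 0, len(y) - 1)
                xs.append(x[src[keep]])
                ys.append(y[keep])
            X = np.vstack(xs)
            Y = np.concatenate(ys)
            ensemble = []
            for _ in range(cfg.n_trees):
                if cfg.per_split_subspace:
                    sub = np.arange(n_feat)
                    max_features = cfg.subspace_dim
                else:
                    sub = np.sort(rng.choice(n_feat, size=cfg.subspace_dim, replace=False))
                    max_features = None
                rows = np.arange(len(Y))
                if cfg.bootstrap:
                    if cfg.balanced_bootstrap:
                        per_class = max(1, len(Y) // len(classes))
                        rows = np.concatenate(
                            [
                                rng.choice(np.flatnonzero(Y == c), size=per_class, replace=True)
                                for c in classes
                                if np.any(Y == c)
                            ]
                        )
                    else:
                        rows = rng.integers(0, len(Y), size=len(Y))
                tree = DecisionTreeClassifier(
                    criterion="entropy",
                    max_features=max_features,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                tree.fit(X[rows][:, sub], Y[rows])
                ensemble.append((tree, sub))
            all_trees.append(ensemble)
        return cls(config=cfg, classes=classes, trees=all_trees)

    # -------------------------------------------------------------- inference
    def _vote_counts(self, features) -> np.ndarray:
        """(T, n_classes) vote counts; each frame collects (2w+1)*N votes."""
        x = _as_matrix(features)
        n = len(x)
        cls_index = {c: i for i, c in enumerate(self.classes)}
        counts = np.zeros((n, len(self.classes)), dtype=np.int32)
        t_idx = np.arange(n)
        w = self.config.window_radius
        for d_i, delta in enumerate(range(-w, w + 1)):
            src = np.clip(t_idx + delta, 0, n - 1)
            x_shift = x[src]
            for tree, sub in self.trees[d_i]:
                pred = tree.predict(x_shift[:, sub])
                for c in np.unique(pred):
                    counts[pred == c, cls_index[str(c)]] += 1
        return counts

    def votes(self, features, t: int) -> list[str]:
        """The multiset of (2w+1)*N class votes for frame ``t``."""
        x = _as_matrix(features)
        n = len(x)
        out = []
        w = self.config.window_radius
        for d_i, delta in enumerate(range(-w, w + 1)):
            src = min(max(t + delta, 0), n - 1)
            row = x[src : src + 1]
            for tree, sub in self.trees[d_i]:
                out.append(str(tree.predict(row[:, sub])[0]))
        return out

    def _mode(self, counts_row: np.ndarray) -> str:
        best = counts_row.max()
        tied = [self.classes[i] for i in np.flatnonzero(counts_row == best)]
        if len(tied) == 1:
            return tied[0]
        # priority tie-break, then lexicographic
        return min(tied, key=lambda c: (self.priorities.get(c, len(self.priorities) + 1), c))

    def classify(self, features, t: int) -> str:
        """Mode of the pooled window votes for frame ``t``."""
        counts = np.zeros(len(self.classes), dtype=int)
        for v in self.votes(features, t):
            counts[self.classes.index(v)] += 1
        return self._mode(counts)

    def classify_sequence(self, features, invalid: np.ndarray | None = None) -> list[str]:
        """Per-frame labels for one pair's ordered feature table.

        ``invalid`` optionally marks flagged frames, which are emitted as
        ``unknown`` without affecting their neighbours' windows.
        """
        counts = self._vote_counts(features)
        labels = [self._mode(row) for row in counts]
        if invalid is not None:
            labels = [UNKNOWN if bad else lab for lab, bad in zip(labels, invalid)]
        return labels

    # ------------------------------------------------------------ persistence
    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TemporalForest":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TemporalForest):
            raise TypeError("archive does not contain a TemporalForest")
        return model
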