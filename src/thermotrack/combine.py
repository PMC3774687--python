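"""Priority-table combination of pairwise labels into per-mouse ethograms.

With M mice each mouse carries M-1 pairwise behaviour labels per frame (one
per possible target). A fixed priority order over the eight classes picks the
single reported behaviour: contact behaviours dominate locomotion and rest, so
e.g. {Nose2Body, StandAlone} collapses to Nose2Body. StandTogether is kept in
its own aggregate bucket in summaries, since its social/non-social status is
debatable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BEHAVIOUR_CLASSES = [
    "Nose2Body",
    "Nose2Nose",
    "Nose2Genitals",
    "Above",
    "Following",
    "WalkAlone",
    "StandAlone",
    "StandTogether",
]

SOCIAL_CLASSES = {"Nose2Body", "Nose2Nose", "Nose2Genitals", "Above", "Following"}
NONSOCIAL_CLASSES = {"WalkAlone", "StandAlone"}

#: 1 = highest priority; contact behaviours dominate locomotion/rest
DEFAULT_PRIORITIES = {
    "Above": 1,
    "Nose2Genitals": 2,
    "Nose2Nose": 3,
    "Nose2Body": 4,
    "Following": 5,
    "StandTogether": 6,
    "WalkAlone": 7,
    "StandAlone": 8,
}


@dataclass
class PriorityTable:
    priorities: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PRIORITIES))

    def __post_init__(self) -> None:
        if set(self.priorities) != set(BEHAVIOUR_CLASSES):
            raise ValueError("priority table must cover exactly the eight classes")
        if len(set(self.priorities.values())) != len(self.priorities):
            raise ValueError("priorities must be injective")

    def rank(self, label: str) -> int:
        return self.priorities[label]


def combine_mouse(labels, table: PriorityTable | None = None) -> str:
    """Collapse the pairwise labels of one mouse at one frame.

    Returns the label with the smallest priority number; ``unknown`` labels
    are ignored unless all inputs are unknown.
    """
    table = table or PriorityTable()
    labels = list(labels)
    if not labels:
        raise ValueError("combine_mouse needs at least one pairwise label (M >= 2)")
    known = [l for l in labels if l != "unknown"]
    if not known:
        return "unknown"
    return min(known, key=table.rank)


def build_ethogram(
    pair_tracks: dict[tuple[int, int], list[str]],
    period: float,
    table: PriorityTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse per-frame labels plus per-class total durations.

    ``pair_tracks`` maps ordered pairs (ref, target) to per-frame label lists
    (aligned on frames, ``unknown`` at gaps). Durations are label counts times
    the frame period; unknown frames are excluded from class durations and
    reported in their own row, so durations plus unknown always sum to the
    video length exactly.
    """
    table = table or PriorityTable()
    mice = sorted({r for r, _ in pair_tracks})
    n = len(next(iter(pair_tracks.values())))
    rows = []
    for m in mice:
        tracks = [v for (r, _), v in pair_tracks.items() if r == m]
        for t in range(n):
            rows.append((t, m, combine_mouse([tr[t] for tr in tracks], table)))
    ethogram = pd.DataFrame(rows, columns=["frame", "mouse_id", "label"])

    dur_rows = []
    for m in mice:
        sub = ethogram[ethogram.mouse_id == m]
        counts = sub.label.value_counts()
        for cls in BEHAVIOUR_CLASSES + ["unknown"]:
            c = int(counts.get(cls, 0))
            # occurrence count: number of maximal runs of the class
            lab = (sub.label == cls).to_numpy()
            occurrences = int(np.count_nonzero(lab[1:] & ~lab[:-1]) + (1 if lab.size and lab[0] else 0))
            dur_rows.append((m, cls, c * period, occurrences))
    durations = pd.DataFrame(
        dur_rows, columns=["mouse_id", "class", "seconds", "occurrences"]
    )
    return ethogram, durations
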