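"""Per-component BIES position statistics.

Each component's position counts over the annotated dictionary are modelled
as a multinomial (n, pi_B, pi_I, pi_E, pi_S): n independent trials, each
placing the component at exactly one of the four positions.  The pi are the
maximum-likelihood estimates count/n.  No smoothing is applied: a position
never observed in the dictionary has probability exactly 0 and is not a
permissible label for that component during recognition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Tuple, Union

import pandas as pd

from .dictionary import AnnotatedPhrase, Label

__all__ = [
    "PositionStats",
    "PositionTable",
    "accumulate_position_counts",
    "position_probabilities",
]

_LABEL_INDEX = {Label.B: 0, Label.I: 1, Label.E: 2, Label.S: 3}


@dataclass(frozen=True)
class PositionStats:
    """Multinomial position counts for one component.

    ``counts`` is (n_B, n_I, n_E, n_S); ``n`` the total number of trials.
    """

    component: str
    counts: Tuple[int, int, int, int]

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def probs(self) -> Tuple[float, float, float, float]:
        """MLE (pi_B, pi_I, pi_E, pi_S) = counts / n."""
        return position_probabilities(self)

    def prob(self, label: Label) -> float:
        return self.probs[_LABEL_INDEX[label]]

    def permissible_labels(self) -> set:
        """In-phrase labels with nonzero probability, plus O."""
        labels = {lab for lab, c in zip(_LABEL_INDEX, self.counts) if c > 0}
        labels.add(Label.O)
        return labels


def position_probabilities(stats: PositionStats) -> Tuple[float, float, float, float]:
    """Maximum-likelihood position probabilities for one component."""
    n = stats.n
    if n < 1:
        raise ValueError(f"component {stats.component!r} has no observations")
    return tuple(c / n for c in stats.counts)


class PositionTable(Dict[str, PositionStats]):
    """Mapping component -> PositionStats with TSV persistence."""

    def prob(self, component: str, label: Label) -> float:
        """pi_label for a component; 0.0 for out-of-vocabulary components."""
        stats = self.get(component)
        if stats is None:
            return 0.0
        return stats.prob(label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": s.component, "n_B": s.counts[0], "n_I": s.counts[1],
             "n_E": s.counts[2], "n_S": s.counts[3]}
            for s in self.values()
        ]
        return pd.DataFrame(rows, columns=["component", "n_B", "n_I", "n_E", "n_S"])

    def save(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PositionTable":
        df = pd.read_csv(path, sep="\t", dtype={"component": str})
        table = cls()
        for row in df.itertuples(index=False):
            stats = PositionStats(
                component=str(row.component),
                counts=(int(row.n_B), int(row.n_I), int(row.n_E), int(row.n_S)),
            )
            table[stats.component] = stats
        return table


def accumulate_position_counts(annotated: Iterable[AnnotatedPhrase]) -> PositionTable:
    """Tally BIES occurrences per component over an annotated dictionary.

    Every (component, label) occurrence adds one trial to that component's
    multinomial.  Components never seen are absent from the table.
    """
    annotated = list(annotated)
    if not annotated:
        raise ValueError("cannot estimate a position model from no phrases")
    counts: Dict[str, List[int]] = {}
    for ap in annotated:
        for component, label in ap.items():
            row = counts.setdefault(component, [0, 0, 0, 0])
            row[_LABEL_INDEX[label]] += 1
    table = PositionTable()
    for component, row in counts.items():
        table[component] = PositionStats(component=component, counts=tuple(row))
    return table
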