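"""Independent brute-force oracle for extraction.

Enumerates every raw labeling in the full product space of per-token label
sets, validates it with a regular-expression grammar, normalizes
consecutive-B/E runs, scores subsequences with its own arithmetic, applies
the utility filter, and returns the emissions of the best labeling.  Shares
no code with the recognizer's segment dynamic program.
"""

from __future__ import annotations

import itertools
import re
from typing import List, Optional, Tuple

from comd import Label
from comd.interaction import InteractionModel
from comd.position import PositionTable
from comd.recognizer import Extraction, ExtractorConfig, TokenizedSentence

_VALID = re.compile(r"(?:O|S|B+[IO]*E+)*")
_SPAN = re.compile(r"B+[IO]*E+")


def candidate_sets(sentence, stats, interaction) -> List[List[str]]:
    sets: List[List[str]] = []
    for tok, kept in zip(sentence.tokens, sentence.kept):
        labels = {"O"}
        entry = stats.get(tok)
        if kept and entry is not None:
            for lab, count in zip("BIES", entry.counts):
                if count > 0:
                    labels.add(lab)
        if (entry is not None and entry.counts[1] > 0) or (
            interaction is not None and tok in interaction
        ):
            labels.add("I")
        sets.append(sorted(labels))
    return sets


def _normalize(labeling: str) -> Tuple[str, List[Tuple[int, int]], List[int]]:
    """Collapse B/E runs; return (normalized labels, spans, singles)."""
    norm = list(labeling)
    spans = []
    for m in _SPAN.finditer(labeling):
        s, e = m.span()
        for t in range(s + 1, e - 1):
            if norm[t] in "BE":
                norm[t] = "I"
        norm[s], norm[e - 1] = "B", "E"
        spans.append((s, e))
    singles = [i for i, lab in enumerate(labeling) if lab == "S"]
    return "".join(norm), spans, singles


def brute_force_extract(
    sentence: TokenizedSentence,
    stats: PositionTable,
    interaction: Optional[InteractionModel],
    config: ExtractorConfig,
) -> List[Extraction]:
    sets = candidate_sets(sentence, stats, interaction)
    tokens = sentence.tokens

    def pi(tok: str, lab: str) -> float:
        entry = stats.get(tok)
        if entry is None:
            return 0.0
        counts = dict(zip("BIES", entry.counts))
        return counts[lab] / entry.n

    best_key = None
    best = None
    for labels in itertools.product(*sets):
        labeling = "".join(labels)
        if not _VALID.fullmatch(labeling):
            continue
        norm, spans, singles = _normalize(labeling)
        score = sum(pi(tokens[i], "S") for i in singles)
        score += sum(pi(tokens[s], "B") * pi(tokens[e - 1], "E") for s, e in spans)
        coverage = len(singles) + sum(e - s for s, e in spans)
        segs = sorted([(i, i + 1) for i in singles] + spans)
        starts = tuple(-s for s, _ in segs)
        ends = tuple(-e for _, e in segs)
        non_o = sum(1 for lab in norm if lab != "O")
        key = (score, coverage, starts, ends, non_o)
        if best_key is None or key > best_key:
            best_key = key
            best = (norm, segs)
    assert best is not None  # the all-O labeling is always valid
    norm, segs = best

    out: List[Extraction] = []
    for s, e in segs:
        if e - s == 1:
            indices = [s]
        else:
            first, last = tokens[s], tokens[e - 1]
            indices = [s]
            for t in range(s + 1, e - 1):
                if norm[t] != "I":
                    continue
                if config.mode == "no-interaction":
                    indices.append(t)
                    continue
                if interaction is None or any(
                    w not in interaction for w in (first, tokens[t], last)
                ):
                    continue
                util = 0.5 * (
                    interaction.score(first, tokens[t])
                    + interaction.score(tokens[t], last)
                )
                if util >= config.delta:
                    indices.append(t)
            indices.append(e - 1)
        out.append(
            Extraction(
                record_id=sentence.record_id,
                phrase=config.joiner.join(tokens[i] for i in indices),
                component_indices=tuple(indices),
                source_span=(s, e),
            )
        )
    return out
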