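"""IoU-based evaluation of extracted phrases, plus dictionary baselines.

An extracted phrase counts as correct when its string IoU with a gold
phrase reaches the threshold epsilon; matching is one-to-one greedy in
descending IoU.  Micro metrics pool true/false positives and false
negatives over all records; macro metrics average per-record precision and
recall over the record set and combine them with the harmonic mean.  All
rates are percentages.

IoU between two strings is defined on character multisets:
|intersection| / |union|, which degrades gracefully for partially
overlapping phrases and is 1 for identical strings.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .dictionary import SymptomPhrase
from .recognizer import Extraction

__all__ = [
    "EvalConfig",
    "RecordScore",
    "EvalReport",
    "iou",
    "match_and_count",
    "micro_metrics",
    "macro_metrics",
    "evaluate",
    "baseline_dictionary_lookup",
    "baseline_bdmm",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    """epsilon: IoU threshold; matches require IoU >= epsilon."""

    epsilon: float = 0.6
    matching: str = "greedy-best-iou"

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.matching != "greedy-best-iou":
            raise ValueError(f"unknown matching scheme {self.matching!r}")


def iou(a: str, b: str) -> float:
    """Character-multiset intersection over union; both empty -> 1."""
    ca, cb = Counter(a), Counter(b)
    inter = sum((ca & cb).values())
    union = sum((ca | cb).values())
    if union == 0:
        return 1.0
    return inter / union


def match_and_count(
    extracted: Sequence[str],
    gold: Sequence[str],
    config: Optional[EvalConfig] = None,
) -> Tuple[int, int, int]:
    """Greedy one-to-one matching: (TP, FP, FN) for one record.

    Pairs are taken in descending IoU order (ties: earlier extraction, then
    earlier gold), each side used at most once; a pair counts as a true
    positive when IoU >= epsilon.
    """
    config = config or EvalConfig()
    pairs = [
        (iou(e, g), ei, gi)
        for ei, e in enumerate(extracted)
        for gi, g in enumerate(gold)
    ]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_e: set = set()
    used_g: set = set()
    tp = 0
    for score, ei, gi in pairs:
        if score < config.epsilon:
            break
        if ei in used_e or gi in used_g:
            continue
        used_e.add(ei)
        used_g.add(gi)
        tp += 1
    fp = len(extracted) - tp
    fn = len(gold) - tp
    return tp, fp, fn


def _rate(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s; reporting 0", what)
        return 0.0
    return num / den * 100.0


def _f1(p: float, r: float) -> float:
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def micro_metrics(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """Pooled precision, recall and F1, in percent."""
    p = _rate(tp, tp + fp, "micro precision")
    r = _rate(tp, tp + fn, "micro recall")
    return p, r, _f1(p, r)


def macro_metrics(
    per_record: Sequence[Tuple[float, float]],
) -> Tuple[float, float, float]:
    """Average per-record (P_s, R_s) percentages over |S|, then harmonic F1."""
    if not per_record:
        raise ValueError("macro metrics need at least one record")
    p = sum(ps for ps, _ in per_record) / len(per_record)
    r = sum(rs for _, rs in per_record) / len(per_record)
    return p, r, _f1(p, r)


@dataclass(frozen=True)
class RecordScore:
    record_id: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return _rate(self.tp, self.tp + self.fp, f"precision of {self.record_id}")

    @property
    def recall(self) -> float:
        return _rate(self.tp, self.tp + self.fn, f"recall of {self.record_id}")


@dataclass(frozen=True)
class EvalReport:
    """Per-record counts plus pooled micro and averaged macro metrics."""

    config: EvalConfig
    records: Tuple[RecordScore, ...]
    micro: Tuple[float, float, float]
    macro: Tuple[float, float, float]

    @property
    def totals(self) -> Tuple[int, int, int]:
        return (
            sum(r.tp for r in self.records),
            sum(r.fp for r in self.records),
            sum(r.fn for r in self.records),
        )

    @property
    def micro_f1(self) -> float:
        return self.micro[2]

    @property
    def macro_f1(self) -> float:
        return self.macro[2]

    def summary(self) -> str:
        tp, fp, fn = self.totals
        lines = [
            f"epsilon={self.config.epsilon}  records={len(self.records)}  "
            f"TP={tp} FP={fp} FN={fn}",
            "micro: P={:.2f} R={:.2f} F1={:.2f}".format(*self.micro),
            "macro: P={:.2f} R={:.2f} F1={:.2f}".format(*self.macro),
        ]
        return "\n".join(lines)


def evaluate(
    predictions: Dict[str, Sequence[str]],
    gold: Dict[str, Sequence[str]],
    config: Optional[EvalConfig] = None,
) -> EvalReport:
    """Score predicted phrase strings against gold, record by record.

    ``predictions`` and ``gold`` map record id -> phrase list; records
    present in either mapping are evaluated (missing side = empty list).
    """
    config = config or EvalConfig()
    ids = sorted(set(predictions) | set(gold))
    if not ids:
        raise ValueError("no records to evaluate")
    records = []
    per_record = []
    n_zero = 0
    for rid in ids:
        tp, fp, fn = match_and_count(
            list(predictions.get(rid, ())), list(gold.get(rid, ())), config
        )
        records.append(RecordScore(record_id=rid, tp=tp, fp=fp, fn=fn))
        n_zero += (tp + fp == 0) + (tp + fn == 0)
        p_s = tp / (tp + fp) * 100.0 if tp + fp else 0.0
        r_s = tp / (tp + fn) * 100.0 if tp + fn else 0.0
        per_record.append((p_s, r_s))
    if n_zero:
        logger.warning(
            "%d per-record rates had zero denominators; reported as 0", n_zero
        )
    totals = (
        sum(r.tp for r in records),
        sum(r.fp for r in records),
        sum(r.fn for r in records),
    )
    micro = micro_metrics(*totals)
    macro = macro_metrics(per_record)
    return EvalReport(config=config, records=tuple(records), micro=micro, macro=macro)


# --------------------------------------------------------------------------
# dictionary baselines
# --------------------------------------------------------------------------

def baseline_dictionary_lookup(
    sentence: str, phrases: Sequence[SymptomPhrase], record_id: str = ""
) -> List[Extraction]:
    """Exact string matching: every maximal occurrence of a dictionary
    phrase in the raw sentence, longest-leftmost on overlap."""
    entries = sorted({p.raw for p in phrases}, key=len, reverse=True)
    out: List[Extraction] = []
    i = 0
    n = len(sentence)
    while i < n:
        hit = None
        for entry in entries:
            if entry and sentence.startswith(entry, i):
                hit = entry
                break
        if hit is None:
            i += 1
            continue
        out.append(
            Extraction(
                record_id=record_id,
                phrase=hit,
                component_indices=tuple(range(i, i + len(hit))),
                source_span=(i, i + len(hit)),
            )
        )
        i += len(hit)
    return out


def _forward_mm(sentence: str, entries: set, max_len: int) -> List[Tuple[int, int]]:
    segments = []
    i = 0
    while i < len(sentence):
        for L in range(min(max_len, len(sentence) - i), 0, -1):
            if L == 1 or sentence[i : i + L] in entries:
                segments.append((i, i + L))
                i += L
                break
    return segments


def _reverse_mm(sentence: str, entries: set, max_len: int) -> List[Tuple[int, int]]:
    segments = []
    j = len(sentence)
    while j > 0:
        for L in range(min(max_len, j), 0, -1):
            if L == 1 or sentence[j - L : j] in entries:
                segments.append((j - L, j))
                j -= L
                break
    segments.reverse()
    return segments


def baseline_bdmm(
    sentence: str, phrases: Sequence[SymptomPhrase], record_id: str = ""
) -> List[Extraction]:
    """Bidirectional maximal matching segmentation baseline.

    Forward and reverse maximal matching are each run over the sentence
    against the dictionary; the direction with fewer segments wins (ties:
    fewer single-character segments, then forward).  Segments that are
    dictionary entries are emitted as extractions.
    """
    if not sentence:
        return []
    entries = {p.raw for p in phrases if p.raw}
    max_len = max((len(e) for e in entries), default=1)
    fwd = _forward_mm(sentence, entries, max_len)
    rev = _reverse_mm(sentence, entries, max_len)

    def singles(segs: List[Tuple[int, int]]) -> int:
        return sum(1 for s, e in segs if e - s == 1)

    chosen = fwd
    if (len(rev), singles(rev)) < (len(fwd), singles(fwd)):
        chosen = rev
    return [
        Extraction(
            record_id=record_id,
            phrase=sentence[s:e],
            component_indices=tuple(range(s, e)),
            source_span=(s, e),
        )
        for s, e in chosen
        if sentence[s:e] in entries
    ]
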