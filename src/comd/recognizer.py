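"""Candidate segmentation and symptom phrase extraction.

Given a sentence, each retained token receives the set of position labels
its dictionary statistics permit (B/I/E/S wherever the corresponding pi is
nonzero, plus O for "outside").  A candidate segmentation is a labeling
whose non-O labels form non-overlapping subsequences, each either a Single
token or a span running from a Begin token to an End token.  Segmentations
are scored by the boundary function

    score(l_1, ..., l_q) = sum_i score(l_i),
    score(l_i) = pi_S(w)                    for a single token w
               = pi_B(first) * pi_E(last)   for a span,

the highest-scoring segmentation is selected, and each span's intermediate
components are then kept or discarded by their utility — the mean
interaction score with the two boundary components — against the threshold
delta.  Kept components are concatenated into the extracted phrase, which
is how disjoint colloquial mentions ("feet ... icy cold ... pain") are
reassembled into a standard-form phrase.

Consecutive Begin labels collapse to the leftmost token and consecutive End
labels to the rightmost, so boundary-capable tokens can still sit inside a
span.  The selection itself is an exact dynamic program over non-overlapping
segments (ties broken by larger token coverage, then leftmost starts), so no
beam approximation is needed at realistic sentence lengths; an exhaustive
enumerator and an optional beam are provided for inspection and testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .dictionary import Label
from .interaction import InteractionModel
from .position import PositionTable
from .tokenizers import Tokenizer, whitespace_tokenizer

__all__ = [
    "SENTENCE_TERMINATORS",
    "FilterConfig",
    "ExtractorConfig",
    "TokenizedSentence",
    "LabelCandidates",
    "Segment",
    "CandidateSegmentation",
    "Extraction",
    "preprocess",
    "assign_labels",
    "candidate_segments",
    "enumerate_segmentations",
    "score_segmentation",
    "normalize_boundaries",
    "utility",
    "extract",
]

#: Default sentence terminators: CJK and ASCII stops, plus newline.
SENTENCE_TERMINATORS = frozenset("。！？!?；;\n")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Token filters applied during preprocessing.

    ``known_vocabulary`` — tokens recognised by the trained models (position
    table or embedding); ``None`` disables the check.  ``common`` and
    ``rare`` are explicit stop-sets, typically built from corpus frequencies
    with :meth:`from_corpus` (ceiling: top 0.1% of document frequency;
    floor: absolute count below 2).
    """

    known_vocabulary: Optional[FrozenSet[str]] = None
    common: FrozenSet[str] = frozenset()
    rare: FrozenSet[str] = frozenset()

    def keeps(self, token: str) -> bool:
        if token in self.common or token in self.rare:
            return False
        if self.known_vocabulary is not None and token not in self.known_vocabulary:
            return False
        return True

    @classmethod
    def from_corpus(
        cls,
        texts: Sequence[str],
        tokenizer: Tokenizer = whitespace_tokenizer,
        known_vocabulary: Optional[Iterable[str]] = None,
        common_top_fraction: float = 0.001,
        rare_min_count: int = 2,
    ) -> "FilterConfig":
        """Derive common/rare stop-sets from corpus frequencies."""
        doc_freq: Dict[str, int] = {}
        count: Dict[str, int] = {}
        for text in texts:
            tokens = tokenizer(text)
            for tok in tokens:
                count[tok] = count.get(tok, 0) + 1
            for tok in set(tokens):
                doc_freq[tok] = doc_freq.get(tok, 0) + 1
        n_common = int(len(doc_freq) * common_top_fraction)
        by_df = sorted(doc_freq, key=lambda t: (-doc_freq[t], t))
        common = frozenset(by_df[:n_common])
        rare = frozenset(t for t, c in count.items() if c < rare_min_count)
        known = frozenset(known_vocabulary) if known_vocabulary is not None else None
        return cls(known_vocabulary=known, common=common, rare=rare)


@dataclass(frozen=True)
class ExtractorConfig:
    """Extraction settings.

    mode : 'full' (position + interaction), 'no-interaction' (keep every
        intermediate), or 'no-position' (interaction-only grouping).
    delta : utility threshold below which an intermediate is discarded.
    min_segment_score : floor each emitted subsequence's own boundary score
        must exceed (0 preserves the plain scoring formula).
    joiner : string used to concatenate kept components into the phrase
        ("" matches unsegmented Chinese output).
    """

    mode: str = "full"
    delta: float = 0.2
    min_segment_score: float = 0.0
    joiner: str = ""
    max_exhaustive_tokens: int = 25

    def __post_init__(self) -> None:
        if self.mode not in ("full", "no-interaction", "no-position"):
            raise ValueError(f"unknown mode {self.mode!r}")


# --------------------------------------------------------------------------
# sentence containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TokenizedSentence:
    """A tokenized sentence with its per-token keep mask."""

    record_id: str
    tokens: Tuple[str, ...]
    kept: Tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        kept = self.kept if self.kept else (True,) * len(self.tokens)
        object.__setattr__(self, "kept", tuple(kept))
        if len(self.kept) != len(self.tokens):
            raise ValueError("keep mask and tokens differ in length")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class LabelCandidates:
    """Per-token permissible label sets (every set contains O)."""

    sentence: TokenizedSentence
    sets: Tuple[FrozenSet[Label], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(frozenset(s) for s in self.sets))
        if len(self.sets) != len(self.sentence):
            raise ValueError("one label set per token required")


@dataclass(frozen=True, order=True)
class Segment:
    """A half-open token span: single (length 1, label S) or a B..E span."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("segment must be a non-empty half-open range")

    @property
    def single(self) -> bool:
        return self.end - self.start == 1

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateSegmentation:
    """A normalized labeling of a sentence into segments plus O tokens."""

    sentence: TokenizedSentence
    segments: Tuple[Segment, ...]
    labels: Tuple[Label, ...]
    score: float = 0.0

    @property
    def q(self) -> int:
        return len(self.segments)

    @property
    def coverage(self) -> int:
        """Total number of tokens covered by segments."""
        return sum(len(s) for s in self.segments)


@dataclass(frozen=True)
class Extraction:
    """One extracted symptom phrase.

    ``component_indices`` are the sentence token indices concatenated into
    the phrase (strictly increasing); ``source_span`` is the half-open token
    range of the originating segment.
    """

    record_id: str
    phrase: str
    component_indices: Tuple[int, ...]
    source_span: Tuple[int, int]


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess(
    text: str,
    tokenizer: Tokenizer = whitespace_tokenizer,
    filters: Optional[FilterConfig] = None,
    record_id: str = "",
    terminators: FrozenSet[str] = SENTENCE_TERMINATORS,
) -> List[TokenizedSentence]:
    """Split text into sentences, tokenize, and apply the keep filters."""
    filters = filters or FilterConfig()
    sentences: List[TokenizedSentence] = []
    buf: List[str] = []
    pieces: List[str] = []
    for ch in text:
        if ch in terminators:
            pieces.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    pieces.append("".join(buf))
    for piece in pieces:
        tokens = tuple(tokenizer(piece))
        if not tokens:
            continue
        kept = tuple(filters.keeps(t) for t in tokens)
        sentences.append(
            TokenizedSentence(record_id=record_id, tokens=tokens, kept=kept)
        )
    return sentences


# --------------------------------------------------------------------------
# label assignment
# --------------------------------------------------------------------------

def assign_labels(
    sentence: TokenizedSentence,
    stats: PositionTable,
    interaction: Optional[InteractionModel] = None,
) -> LabelCandidates:
    """Permissible labels per token.

    A kept token may take any in-phrase label whose dictionary probability
    is nonzero.  A token may additionally take I — whether kept or filtered
    out — if it has nonzero pi_I or an embedding: colloquial fillers with
    vectors can sit inside a span and be judged by their utility, while
    tokens the models have never seen stay O and are skipped outright.
    """
    sets: List[Set[Label]] = []
    for token, kept in zip(sentence.tokens, sentence.kept):
        labels: Set[Label] = {Label.O}
        entry = stats.get(token)
        if kept and entry is not None:
            labels |= {lab for lab in entry.permissible_labels() if lab is not Label.O}
        i_eligible = (entry is not None and entry.prob(Label.I) > 0) or (
            interaction is not None and token in interaction
        )
        if i_eligible:
            labels.add(Label.I)
        sets.append(frozenset(labels))
    return LabelCandidates(sentence=sentence, sets=tuple(sets))


# --------------------------------------------------------------------------
# segmentation enumeration and scoring
# --------------------------------------------------------------------------

def candidate_segments(
    candidates: LabelCandidates,
    stats: PositionTable,
    min_segment_score: float = 0.0,
) -> List[Tuple[Segment, float]]:
    """All permissible segments with their boundary scores.

    Singles where S is permissible; spans (s, e) wherever token s can be B
    and token e-1 can be E.  Segments whose own score does not exceed
    ``min_segment_score`` are excluded (default floor 0 excludes nothing,
    since permissible boundaries have strictly positive probabilities).
    """
    tokens = candidates.sentence.tokens
    n = len(tokens)
    out: List[Tuple[Segment, float]] = []
    for i in range(n):
        if Label.S in candidates.sets[i]:
            w = stats.prob(tokens[i], Label.S)
            if w > min_segment_score:
                out.append((Segment(i, i + 1), w))
    begins = [i for i in range(n) if Label.B in candidates.sets[i]]
    ends = [j for j in range(n) if Label.E in candidates.sets[j]]
    for i in begins:
        pb = stats.prob(tokens[i], Label.B)
        for j in ends:
            if j <= i:
                continue
            w = pb * stats.prob(tokens[j], Label.E)
            if w > min_segment_score:
                out.append((Segment(i, j + 1), w))
    out.sort(key=lambda sw: (sw[0].start, sw[0].end))
    return out


def _segment_labels(
    candidates: LabelCandidates, segments: Sequence[Segment]
) -> Tuple[Label, ...]:
    """Normalized labels for a chosen segment set: interiors take I where
    permissible, otherwise remain O (and are skipped at emission)."""
    labels = [Label.O] * len(candidates.sentence)
    for seg in segments:
        if seg.single:
            labels[seg.start] = Label.S
        else:
            labels[seg.start] = Label.B
            labels[seg.end - 1] = Label.E
            for t in range(seg.start + 1, seg.end - 1):
                if Label.I in candidates.sets[t]:
                    labels[t] = Label.I
    return tuple(labels)


def _selection_key(score: float, segments: Sequence[Segment]):
    """Total order used to select among candidate segmentations: higher
    score, then larger token coverage, then leftmost span starts/ends."""
    coverage = sum(len(s) for s in segments)
    starts = tuple(s.start for s in segments)
    ends = tuple(s.end for s in segments)
    return (score, coverage, tuple(-x for x in starts), tuple(-x for x in ends))


def enumerate_segmentations(
    candidates: LabelCandidates,
    stats: PositionTable,
    min_segment_score: float = 0.0,
    beam_width: Optional[int] = None,
) -> List[CandidateSegmentation]:
    """All valid (normalized) segmentations, best-first.

    With ``beam_width`` set, a left-to-right beam keeps only the top
    ``beam_width`` partial segmentations at each token position; a width at
    least the number of valid segmentations reproduces the exhaustive list.
    """
    segs = candidate_segments(candidates, stats, min_segment_score)
    n = len(candidates.sentence)
    by_start: Dict[int, List[Tuple[Segment, float]]] = {}
    for seg, w in segs:
        by_start.setdefault(seg.start, []).append((seg, w))

    # partial states: (chosen segments, score); advance position by position
    states: List[Tuple[Tuple[Segment, ...], float]] = [((), 0.0)]
    for pos in range(n):
        nxt: List[Tuple[Tuple[Segment, ...], float]] = []
        for chosen, score in states:
            occupied_until = chosen[-1].end if chosen else 0
            if pos < occupied_until:
                nxt.append((chosen, score))  # inside an already chosen segment
                continue
            nxt.append((chosen, score))  # token stays O
            for seg, w in by_start.get(pos, []):
                nxt.append((chosen + (seg,), score + w))
        # dedupe (a state can be reached once per position here, but keep tidy)
        nxt.sort(key=lambda cs: _selection_key(cs[1], cs[0]), reverse=True)
        if beam_width is not None:
            nxt = nxt[:beam_width]
        states = nxt

    out = [
        CandidateSegmentation(
            sentence=candidates.sentence,
            segments=chosen,
            labels=_segment_labels(candidates, chosen),
            score=score,
        )
        for chosen, score in states
    ]
    return out


def score_segmentation(seg: CandidateSegmentation, stats: PositionTable) -> float:
    """Boundary score: sum over segments of pi_S, or pi_B(first)*pi_E(last)."""
    tokens = seg.sentence.tokens
    total = 0.0
    for s in seg.segments:
        if s.single:
            total += stats.prob(tokens[s.start], Label.S)
        else:
            total += stats.prob(tokens[s.start], Label.B) * stats.prob(
                tokens[s.end - 1], Label.E
            )
    return total


def normalize_boundaries(seg: CandidateSegmentation) -> CandidateSegmentation:
    """Collapse consecutive B labels to the leftmost start and consecutive E
    labels to the rightmost end; interior B/E relabel to I."""
    labels = list(seg.labels)
    n = len(labels)
    new_labels = list(labels)
    segments: List[Segment] = []
    i = 0
    while i < n:
        lab = labels[i]
        if lab is Label.S:
            segments.append(Segment(i, i + 1))
            i += 1
        elif lab is Label.B:
            start = i
            while i < n and labels[i] is Label.B:
                i += 1
            # advance through interior to the E run
            while i < n and labels[i] in (Label.I, Label.O):
                i += 1
            if i >= n or labels[i] is not Label.E:
                raise ValueError("span beginning at token %d never closes" % start)
            while i < n and labels[i] is Label.E:
                i += 1
            end = i
            for t in range(start + 1, end - 1):
                if new_labels[t] in (Label.B, Label.E):
                    new_labels[t] = Label.I
            new_labels[start] = Label.B
            new_labels[end - 1] = Label.E
            segments.append(Segment(start, end))
        elif lab is Label.O:
            i += 1
        else:
            raise ValueError(f"dangling {lab} label outside any span at token {i}")
    return replace(seg, labels=tuple(new_labels), segments=tuple(segments))


# --------------------------------------------------------------------------
# utility filtering and extraction
# --------------------------------------------------------------------------

def utility(
    w_first: str, w_mid: str, w_last: str, interaction: InteractionModel
) -> float:
    """Mean interaction of an intermediate with the two boundary components."""
    return 0.5 * (
        interaction.score(w_first, w_mid) + interaction.score(w_mid, w_last)
    )


def _argmax_segmentation(
    candidates: LabelCandidates,
    stats: PositionTable,
    min_segment_score: float,
) -> CandidateSegmentation:
    """Exact best segmentation by dynamic programming over segments."""
    segs = candidate_segments(candidates, stats, min_segment_score)
    n = len(candidates.sentence)
    by_start: Dict[int, List[Tuple[Segment, float]]] = {}
    for seg, w in segs:
        by_start.setdefault(seg.start, []).append((seg, w))

    @lru_cache(maxsize=None)
    def best(pos: int) -> Tuple[float, Tuple[Segment, ...]]:
        if pos >= n:
            return 0.0, ()
        score, chosen = best(pos + 1)  # token pos stays O
        for seg, w in by_start.get(pos, []):
            s_score, s_chosen = best(seg.end)
            cand = (w + s_score, (seg,) + s_chosen)
            if _selection_key(*cand) > _selection_key(score, chosen):
                score, chosen = cand
        return score, chosen

    score, chosen = best(0)
    best.cache_clear()
    return CandidateSegmentation(
        sentence=candidates.sentence,
        segments=chosen,
        labels=_segment_labels(candidates, chosen),
        score=score,
    )


def _emit_segment(
    seg: Segment,
    segmentation: CandidateSegmentation,
    interaction: Optional[InteractionModel],
    config: ExtractorConfig,
) -> Extraction:
    sentence = segmentation.sentence
    tokens = sentence.tokens
    if seg.single:
        indices = [seg.start]
    else:
        first, last = tokens[seg.start], tokens[seg.end - 1]
        indices = [seg.start]
        for t in range(seg.start + 1, seg.end - 1):
            if segmentation.labels[t] is not Label.I:
                continue  # O inside a span: never part of the phrase
            if config.mode == "no-interaction":
                indices.append(t)
                continue
            if (
                interaction is None
                or tokens[t] not in interaction
                or first not in interaction
                or last not in interaction
            ):
                continue  # utility undefined for OOV: discard
            if utility(first, tokens[t], last, interaction) >= config.delta:
                indices.append(t)
        indices.append(seg.end - 1)
    return Extraction(
        record_id=sentence.record_id,
        phrase=config.joiner.join(tokens[i] for i in indices),
        component_indices=tuple(indices),
        source_span=(seg.start, seg.end),
    )


def _extract_no_position(
    sentence: TokenizedSentence,
    interaction: InteractionModel,
    config: ExtractorConfig,
) -> List[Extraction]:
    """Interaction-only ablation: group kept in-vocabulary tokens whose
    pairwise interaction reaches delta (connected components, size >= 2)."""
    idx = [
        i
        for i, (tok, kept) in enumerate(zip(sentence.tokens, sentence.kept))
        if kept and tok in interaction
    ]
    parent = {i: i for i in idx}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in itertools.combinations(idx, 2):
        if interaction.score(sentence.tokens[a], sentence.tokens[b]) >= config.delta:
            parent[find(a)] = find(b)
    groups: Dict[int, List[int]] = {}
    for i in idx:
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in sorted(groups.values(), key=lambda m: m[0]):
        if len(members) < 2:
            continue
        members.sort()
        out.append(
            Extraction(
                record_id=sentence.record_id,
                phrase=config.joiner.join(sentence.tokens[i] for i in members),
                component_indices=tuple(members),
                source_span=(members[0], members[-1] + 1),
            )
        )
    return out


def extract(
    sentence: TokenizedSentence,
    stats: Optional[PositionTable],
    interaction: Optional[InteractionModel],
    config: Optional[ExtractorConfig] = None,
) -> List[Extraction]:
    """Extract symptom phrases from one tokenized sentence.

    In 'full' and 'no-interaction' modes the highest-scoring normalized
    segmentation is selected and each segment emitted, filtering span
    intermediates by utility in 'full' mode.  'no-position' drops the
    boundary model entirely and groups components by pairwise interaction.
    """
    config = config or ExtractorConfig()
    if len(sentence) == 0:
        return []
    if config.mode == "no-position":
        if interaction is None:
            raise ValueError("no-position mode requires an interaction model")
        return _extract_no_position(sentence, interaction, config)
    if stats is None:
        raise ValueError(f"{config.mode} mode requires a position model")
    candidates = assign_labels(sentence, stats, interaction)
    segmentation = _argmax_segmentation(candidates, stats, config.min_segment_score)
    return [
        _emit_segment(seg, segmentation, interaction, config)
        for seg in segmentation.segments
    ]
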