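"""Symptom dictionary loading and automatic BIES annotation.

A symptom dictionary is a plain-text list of standard symptom phrases, one
per line, used as the only training signal: no corpus annotation exists.
Each phrase is tokenized into *components* (words, or single characters in
character mode) and annotated automatically with BIES position labels —
Begin / Intermediate / End for multi-component phrases, Single for
one-component phrases.  These automatic annotations are what the position
model is estimated from.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

from .tokenizers import Tokenizer, get_tokenizer, strip_punctuation

__all__ = [
    "Label",
    "SymptomPhrase",
    "AnnotatedPhrase",
    "load_dictionary",
    "annotate_bies",
    "annotate_dictionary",
]


class Label(str, enum.Enum):
    """BIES-O position labels for a component within a phrase."""

    B = "B"  # begin of a multi-component phrase
    I = "I"  # intermediate position
    E = "E"  # end of a multi-component phrase
    S = "S"  # single-component phrase
    O = "O"  # outside any phrase ("Other")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The four in-phrase positions, in canonical (B, I, E, S) order.
BIES = (Label.B, Label.I, Label.E, Label.S)


@dataclass(frozen=True)
class SymptomPhrase:
    """A standard symptom phrase split into its components.

    Parameters
    ----------
    raw : str
        The phrase as it appeared in the dictionary (punctuation stripped).
    components : tuple of str
        Ordered tokenizer output; the semantic units of composition.
    granularity : str
        ``"word"`` or ``"character"``.
    """

    raw: str
    components: tuple
    granularity: str = "word"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a SymptomPhrase needs at least one component")
        object.__setattr__(self, "components", tuple(self.components))

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class AnnotatedPhrase:
    """A phrase together with its automatic BIES labels."""

    phrase: SymptomPhrase
    labels: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(self.phrase):
            raise ValueError("labels and components differ in length")

    def items(self):
        """Pairs of (component, label)."""
        return zip(self.phrase.components, self.labels)


def annotate_bies(phrase: SymptomPhrase) -> AnnotatedPhrase:
    """Annotate a phrase with BIES labels from its component count alone.

    A one-component phrase is Single; otherwise the first component is
    Begin, the last is End, and everything in between is Intermediate.
    """
    n = len(phrase)
    if n == 0:
        raise ValueError("cannot annotate an empty phrase")
    if n == 1:
        labels = (Label.S,)
    else:
        labels = (Label.B,) + (Label.I,) * (n - 2) + (Label.E,)
    return AnnotatedPhrase(phrase=phrase, labels=labels)


def annotate_dictionary(phrases: Iterable[SymptomPhrase]) -> List[AnnotatedPhrase]:
    """Annotate every phrase in a dictionary."""
    return [annotate_bies(p) for p in phrases]


def load_dictionary(
    path: Union[str, Path],
    granularity: str = "word",
    tokenizer: Optional[Tokenizer] = None,
) -> List[SymptomPhrase]:
    """Load a symptom dictionary from a one-phrase-per-line UTF-8 file.

    Blank lines are skipped and punctuation characters are stripped before
    tokenization.  Duplicates — phrases whose tokenized component sequences
    coincide — are removed, keeping first occurrence order.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If no phrases remain after filtering.
    """
    tok = tokenizer if tokenizer is not None else get_tokenizer(granularity)
    text = Path(path).read_text(encoding="utf-8")
    phrases = phrases_from_lines(text.splitlines(), granularity, tok)
    if not phrases:
        raise ValueError(f"dictionary {path} is empty after filtering")
    return phrases


def phrases_from_lines(
    lines: Iterable[str],
    granularity: str = "word",
    tokenizer: Optional[Tokenizer] = None,
) -> List[SymptomPhrase]:
    """Build deduplicated phrases from an iterable of raw lines."""
    tok = tokenizer if tokenizer is not None else get_tokenizer(granularity)
    seen = set()
    phrases: List[SymptomPhrase] = []
    for line in lines:
        cleaned = strip_punctuation(line).strip()
        if not cleaned:
            continue
        components = tuple(tok(cleaned))
        if not components or components in seen:
            continue
        seen.add(components)
        phrases.append(
            SymptomPhrase(raw=cleaned, components=components, granularity=granularity)
        )
    return phrases
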