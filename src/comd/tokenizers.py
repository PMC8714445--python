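"""Tokenizer contracts.

The recognizer is tokenizer-agnostic: any callable mapping a string to an
ordered list of component strings can be plugged in.  For Chinese text a
word segmenter would be supplied by the caller; the defaults here cover
whitespace-delimited corpora (word granularity) and per-code-point splitting
(character granularity).
"""

from __future__ import annotations

import unicodedata
from typing import Callable, List

Tokenizer = Callable[[str], List[str]]


def whitespace_tokenizer(text: str) -> List[str]:
    """Split on runs of whitespace. The default word-granularity tokenizer."""
    return text.split()


def character_tokenizer(text: str) -> List[str]:
    """Split into Unicode code points, dropping whitespace."""
    return [ch for ch in text if not ch.isspace()]


def is_punctuation(ch: str) -> bool:
    """True for Unicode punctuation and symbol code points."""
    return unicodedata.category(ch).startswith(("P", "S"))


def strip_punctuation(text: str, extra: str = "") -> str:
    """Remove punctuation (and any ``extra`` characters) from ``text``."""
    return "".join(ch for ch in text if not (is_punctuation(ch) or ch in extra))


def get_tokenizer(granularity: str) -> Tokenizer:
    """Default tokenizer for a granularity: 'word' or 'character'."""
    if granularity == "word":
        return whitespace_tokenizer
    if granularity in ("character", "char"):
        return character_tokenizer
    raise ValueError(f"unknown granularity: {granularity!r}")
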