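"""Skip-gram component embeddings.

Components are embedded with a skip-gram model trained by stochastic
gradient descent with negative sampling: for each (target, context) pair
within a dynamically shrunk window the model raises the score of the true
context and lowers the score of ``negative`` sampled noise components drawn
from the unigram distribution raised to the 3/4 power.  Components that
co-occur, or occur in similar contexts, end up with similar vectors.

Training is plain numpy, single-threaded, and fully deterministic under a
fixed seed, which the downstream clustering and recognition steps rely on
for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from .dictionary import SymptomPhrase

__all__ = ["EmbeddingSpace", "train_embeddings"]


@dataclass
class EmbeddingSpace:
    """A fixed-dimension vector per vocabulary component."""

    index: Dict[str, int]
    vectors: np.ndarray  # shape (V, d)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or len(self.index) != self.vectors.shape[0]:
            raise ValueError("index and vector matrix are inconsistent")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    @property
    def vocabulary(self) -> List[str]:
        return list(self.index)

    def __contains__(self, component: str) -> bool:
        return component in self.index

    def __len__(self) -> int:
        return len(self.index)

    def vector(self, component: str) -> np.ndarray:
        try:
            return self.vectors[self.index[component]]
        except KeyError:
            raise KeyError(f"component {component!r} not in embedding vocabulary")

    def cosine(self, a: str, b: str) -> float:
        """Cosine similarity between two components' vectors."""
        va, vb = self.vector(a), self.vector(b)
        denom = np.linalg.norm(va) * np.linalg.norm(vb)
        if denom == 0.0:
            return 0.0
        return float(va @ vb / denom)

    def save(self, path: Union[str, Path]) -> None:
        """Write word2vec text format: header 'V d', then 'token v1 ... vd'."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self)} {self.d}\n")
            for token, i in self.index.items():
                vec = " ".join(repr(float(x)) for x in self.vectors[i])
                fh.write(f"{token} {vec}\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "EmbeddingSpace":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            index: Dict[str, int] = {}
            vectors = np.empty((n, d))
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                index[parts[0]] = i
                vectors[i] = [float(x) for x in parts[1:]]
        return cls(index=index, vectors=vectors)


def _as_sentences(
    phrases: Sequence[Union[SymptomPhrase, Sequence[str]]],
) -> List[List[str]]:
    sentences = []
    for p in phrases:
        if isinstance(p, SymptomPhrase):
            sentences.append(list(p.components))
        else:
            sentences.append(list(p))
    return sentences


def train_embeddings(
    phrases: Sequence[Union[SymptomPhrase, Sequence[str]]],
    d: int = 500,
    window: int = 5,
    seed: int = 0,
    *,
    epochs: int = 10,
    negative: int = 5,
    lr: float = 0.05,
    min_lr: float = 1e-4,
    min_count: int = 1,
    supplementary: Optional[Sequence[Sequence[str]]] = None,
) -> EmbeddingSpace:
    """Train skip-gram embeddings on dictionary phrases.

    Each phrase contributes its component sequence as one training sentence.
    ``supplementary`` optionally adds unlabeled corpus sentences (token
    lists) to the training stream; it widens the vocabulary to corpus-only
    tokens (e.g. colloquial fillers) without touching the position model.

    Components occurring fewer than ``min_count`` times are dropped.  Raises
    ``ValueError`` if the vocabulary is empty after filtering.
    """
    sentences = _as_sentences(phrases)
    if supplementary is not None:
        sentences += _as_sentences(supplementary)

    counts: Dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = [t for t, c in counts.items() if c >= min_count]
    if not vocab:
        raise ValueError("embedding vocabulary is empty after min-count filtering")
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    # noise distribution ~ count^0.75, as cumulative table for searchsorted
    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())

    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    encoded = [np.array([index[t] for t in s if t in index]) for s in sentences]
    encoded = [s for s in encoded if len(s) > 0]
    total_steps = max(1, epochs * len(encoded))
    step = 0
    order = np.arange(len(encoded))
    for _ in range(epochs):
        rng.shuffle(order)
        for si in order:
            sent = encoded[si]
            alpha = max(min_lr, lr * (1.0 - step / total_steps))
            step += 1
            n = len(sent)
            if n < 2:
                continue
            shrink = rng.integers(1, window + 1, size=n)
            for i in range(n):
                b = shrink[i]
                lo, hi = max(0, i - b), min(n, i + b + 1)
                ctx = np.concatenate([sent[lo:i], sent[i + 1:hi]])
                if len(ctx) == 0:
                    continue
                center = sent[i]
                neg = np.searchsorted(
                    noise_cdf, rng.random((len(ctx), negative))
                )
                targets = np.concatenate([ctx[:, None], neg], axis=1)
                labels = np.zeros_like(targets, dtype=float)
                labels[:, 0] = 1.0
                v_c = w_in[center]                       # (d,)
                out = w_out[targets]                     # (p, 1+neg, d)
                scores = out @ v_c                       # (p, 1+neg)
                g = (labels - _sigmoid(scores)) * alpha  # (p, 1+neg)
                grad_center = np.einsum("pk,pkd->d", g, out)
                np.add.at(
                    w_out,
                    targets.ravel(),
                    (g[..., None] * v_c).reshape(-1, d),
                )
                w_in[center] += grad_center
    return EmbeddingSpace(index=index, vectors=w_in)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clipped for numerical safety at extreme scores
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
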