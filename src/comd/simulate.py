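"""Synthetic dictionaries, corpora and gold annotations.

The generator emulates the statistical structure the recognizer assumes,
without requiring any real (Chinese) data:

* a vocabulary of opaque ASCII components partitioned into topical groups,
  each component carrying a position-role affinity (begin / interior /
  end / single);
* a dictionary of standard phrases drawn as S or B-I*-E compositions, with
  each slot's component sampled from the matching role distribution within
  one group — so components of a group co-occur and acquire similar
  embeddings, while the position model sees role-consistent placements;
* a consultation corpus whose sentences embed phrases (either verbatim
  dictionary entries or freshly recombined, position-legal compositions)
  among colloquial filler tokens drawn from a disjoint vocabulary with its
  own co-occurrence context, so filler utilities are low by construction;
* gold annotations recording each intended phrase string.

Because slots are sampled by role, a component's long-run BIES frequencies
converge to the induced conditional P(position | component), which the
generator computes in closed form and returns as the ground truth for
parameter-recovery tests.

Everything is driven by one numpy Generator seeded from the config, so a
fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .dictionary import SymptomPhrase

__all__ = ["GeneratorConfig", "SyntheticData", "generate_dictionary", "generate_corpus", "generate"]

_ROLES = ("B", "I", "E", "S")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic world.

    n_groups : topical communities of components; phrases never mix groups.
    begin/interior/end/single_per_group : role vocabulary sizes per group.
    n_fillers : size of the disjoint colloquial-filler vocabulary.
    role_purity : probability mass a component keeps on its primary role
        (1.0 = strictly disjoint roles; lower values let boundary-capable
        components also appear in the middle, as real dictionaries do).
    length_probs : distribution of phrase component counts (keys >= 1).
    n_phrases, n_sentences : dictionary and corpus sizes.
    spans_per_sentence : inclusive range of gold phrases per content sentence.
    filler_rate : probability of inserting a filler at each gap inside a
        span and at each boundary around it.
    recombine : sample fresh position-legal phrases for the corpus (True)
        instead of verbatim dictionary entries.
    filler_sentence_fraction : fraction of sentences that are pure filler
        chatter (they give fillers their own embedding context).
    """

    n_groups: int = 3
    begin_per_group: int = 4
    interior_per_group: int = 4
    end_per_group: int = 4
    single_per_group: int = 2
    n_fillers: int = 12
    role_purity: float = 1.0
    length_probs: Tuple[Tuple[int, float], ...] = (
        (1, 0.25), (2, 0.30), (3, 0.25), (4, 0.15), (5, 0.05),
    )
    n_phrases: int = 300
    n_sentences: int = 100
    spans_per_sentence: Tuple[int, int] = (1, 2)
    filler_rate: float = 0.3
    recombine: bool = True
    filler_sentence_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [p for _, p in self.length_probs]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("length_probs must be a probability distribution")
        if any(length < 1 for length, _ in self.length_probs):
            raise ValueError("phrase lengths must be >= 1")
        if not 0.0 <= self.role_purity <= 1.0:
            raise ValueError("role_purity must lie in [0, 1]")
        if any(
            v < 0
            for v in (
                self.n_groups, self.begin_per_group, self.interior_per_group,
                self.end_per_group, self.single_per_group, self.n_fillers,
            )
        ):
            raise ValueError("vocabulary sizes must be non-negative")
        needs = {
            "B": self.begin_per_group,
            "I": self.interior_per_group,
            "E": self.end_per_group,
            "S": self.single_per_group,
        }
        for length, p in self.length_probs:
            if p == 0:
                continue
            if length == 1 and needs["S"] == 0:
                raise ValueError("single-component phrases need single-role components")
            if length >= 2 and (needs["B"] == 0 or needs["E"] == 0):
                raise ValueError("multi-component phrases need begin and end components")
            if length >= 3 and needs["I"] == 0:
                raise ValueError("length >= 3 phrases need interior components")


class _Vocabulary:
    """Role-affinity vocabulary built deterministically from a config."""

    def __init__(self, config: GeneratorConfig):
        self.config = config
        self.components: List[str] = []
        self.group_of: Dict[str, int] = {}
        self.affinity: Dict[str, np.ndarray] = {}  # over (B, I, E, S)
        purity = config.role_purity
        spread = 1.0 - purity
        role_sizes = (
            ("b", "B", config.begin_per_group),
            ("i", "I", config.interior_per_group),
            ("e", "E", config.end_per_group),
            ("s", "S", config.single_per_group),
        )
        for g in range(config.n_groups):
            for prefix, role, size in role_sizes:
                for j in range(size):
                    name = f"{prefix}{g}{chr(ord('a') + j)}"
                    a = np.zeros(4)
                    r = _ROLES.index(role)
                    a[r] = purity
                    if spread > 0:
                        if role in ("B", "E"):
                            a[_ROLES.index("I")] += spread
                        elif role == "I":
                            a[_ROLES.index("B")] += spread / 2
                            a[_ROLES.index("E")] += spread / 2
                        else:  # singles stay single
                            a[r] += spread
                    self.components.append(name)
                    self.group_of[name] = g
                    self.affinity[name] = a
        self.fillers = [f"x{j:02d}" for j in range(config.n_fillers)]
        # per-group, per-role sampling distributions Q_r(c) ∝ affinity
        self.role_members: Dict[Tuple[int, str], Tuple[List[str], np.ndarray]] = {}
        for g in range(config.n_groups):
            members = [c for c in self.components if self.group_of[c] == g]
            for r_idx, role in enumerate(_ROLES):
                weights = np.array([self.affinity[c][r_idx] for c in members])
                total = weights.sum()
                if total > 0:
                    keep = weights > 0
                    names = [m for m, k in zip(members, keep) if k]
                    self.role_members[(g, role)] = (names, weights[keep] / total)

    def sample_slot(self, rng: np.random.Generator, group: int, role: str) -> str:
        names, probs = self.role_members[(group, role)]
        return names[rng.choice(len(names), p=probs)]

    def sample_phrase(self, rng: np.random.Generator, group: Optional[int] = None) -> SymptomPhrase:
        cfg = self.config
        if group is None:
            group = int(rng.integers(cfg.n_groups))
        lengths = [l for l, _ in cfg.length_probs]
        probs = [p for _, p in cfg.length_probs]
        L = lengths[rng.choice(len(lengths), p=probs)]
        if L == 1:
            comps = [self.sample_slot(rng, group, "S")]
        else:
            comps = [self.sample_slot(rng, group, "B")]
            comps += [self.sample_slot(rng, group, "I") for _ in range(L - 2)]
            comps.append(self.sample_slot(rng, group, "E"))
        return SymptomPhrase(raw=" ".join(comps), components=tuple(comps))

    def true_multinomials(self) -> Dict[str, Tuple[float, float, float, float]]:
        """Closed-form induced P(position | component).

        With slot-role sampling, counts(c, r) grows in proportion to
        E[#slots of role r] * Q_r(c); normalising over roles gives the
        multinomial that empirical frequencies converge to.
        """
        cfg = self.config
        e_slots = {
            "B": sum(p for l, p in cfg.length_probs if l >= 2),
            "E": sum(p for l, p in cfg.length_probs if l >= 2),
            "I": sum(p * max(l - 2, 0) for l, p in cfg.length_probs),
            "S": sum(p for l, p in cfg.length_probs if l == 1),
        }
        truth: Dict[str, Tuple[float, float, float, float]] = {}
        for c in self.components:
            g = self.group_of[c]
            rates = np.zeros(4)
            for r_idx, role in enumerate(_ROLES):
                entry = self.role_members.get((g, role))
                if entry is None:
                    continue
                names, probs = entry
                if c in names:
                    rates[r_idx] = e_slots[role] * probs[names.index(c)]
            total = rates.sum()
            if total > 0:
                rates = rates / total
            truth[c] = tuple(rates)
        return truth


@dataclass
class SyntheticData:
    """A complete synthetic study: dictionary, corpus and gold spans."""

    config: GeneratorConfig
    phrases: List[SymptomPhrase]
    truth: Dict[str, Tuple[float, float, float, float]]
    sentences: List[Tuple[str, Tuple[str, ...]]]  # (record id, tokens)
    gold: Dict[str, List[str]]
    fillers: List[str]
    group_of: Dict[str, int]

    @property
    def corpus_texts(self) -> Dict[str, str]:
        return {rid: " ".join(tokens) for rid, tokens in self.sentences}

    def write(self, outdir: Union[str, Path]) -> None:
        """Write dictionary.txt, corpus.txt, gold.tsv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "dictionary.txt").write_text(
            "".join(" ".join(p.components) + "\n" for p in self.phrases),
            encoding="utf-8",
        )
        (outdir / "corpus.txt").write_text(
            "".join(f"{rid}\t{' '.join(toks)}\n" for rid, toks in self.sentences),
            encoding="utf-8",
        )
        with open(outdir / "gold.tsv", "w", encoding="utf-8") as fh:
            for rid, phrases in self.gold.items():
                for phrase in phrases:
                    fh.write(f"{rid}\t{phrase}\n")
        payload = {
            "config": {**asdict(self.config),
                       "length_probs": [list(lp) for lp in self.config.length_probs],
                       "spans_per_sentence": list(self.config.spans_per_sentence)},
            "multinomials": {c: list(pi) for c, pi in self.truth.items()},
            "groups": self.group_of,
            "fillers": self.fillers,
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))


def generate_dictionary(
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[SymptomPhrase], Dict[str, Tuple[float, float, float, float]]]:
    """Draw a synthetic dictionary plus the true position multinomials."""
    vocab = _Vocabulary(config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    phrases = [vocab.sample_phrase(rng) for _ in range(config.n_phrases)]
    return phrases, vocab.true_multinomials()


def generate_corpus(
    phrases: Sequence[SymptomPhrase],
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Tuple[str, Tuple[str, ...]]], Dict[str, List[str]]]:
    """Build noisy consultation sentences with gold phrase annotations."""
    if not phrases:
        raise ValueError("corpus generation needs a non-empty dictionary")
    vocab = _Vocabulary(config)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    sentences: List[Tuple[str, Tuple[str, ...]]] = []
    gold: Dict[str, List[str]] = {}

    def filler() -> str:
        return vocab.fillers[int(rng.integers(len(vocab.fillers)))]

    def maybe_fillers(rate: float, max_run: int = 2) -> List[str]:
        out = []
        for _ in range(max_run):
            if rng.random() < rate:
                out.append(filler())
        return out

    lo, hi = config.spans_per_sentence
    for s in range(config.n_sentences):
        rid = f"r{s:04d}"
        use_fillers = config.n_fillers > 0
        if use_fillers and rng.random() < config.filler_sentence_fraction:
            k = int(rng.integers(3, 9))
            tokens = [filler() for _ in range(k)]
            sentences.append((rid, tuple(tokens)))
            gold[rid] = []
            continue
        n_spans = int(rng.integers(lo, hi + 1))
        tokens: List[str] = []
        phrases_here: List[str] = []
        if use_fillers:
            tokens += maybe_fillers(config.filler_rate)
        for _ in range(n_spans):
            if config.recombine:
                phrase = vocab.sample_phrase(rng)
            else:
                phrase = phrases[int(rng.integers(len(phrases)))]
            phrases_here.append("".join(phrase.components))
            comps = list(phrase.components)
            tokens.append(comps[0])
            for comp in comps[1:]:
                if use_fillers and config.filler_rate > 0:
                    tokens += maybe_fillers(config.filler_rate, max_run=1)
                tokens.append(comp)
            if use_fillers:
                tokens += maybe_fillers(config.filler_rate)
        sentences.append((rid, tuple(tokens)))
        gold[rid] = phrases_here
    return sentences, gold


def generate(config: GeneratorConfig) -> SyntheticData:
    """Generate a full synthetic study from one seed."""
    rng = np.random.default_rng(config.seed)
    vocab = _Vocabulary(config)
    phrases = [vocab.sample_phrase(rng) for _ in range(config.n_phrases)]
    sentences, gold = generate_corpus(phrases, config, rng)
    return SyntheticData(
        config=config,
        phrases=phrases,
        truth=vocab.true_multinomials(),
        sentences=sentences,
        gold=gold,
        fillers=list(vocab.fillers),
        group_of=dict(vocab.group_of),
    )
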