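"""End-to-end model bundle: train once, extract from any text.

``ComDModel`` holds the three trained artefacts — the position table, the
embedding space and the interaction model — plus the tokenizer and default
extraction settings, and exposes the complete recognition pipeline
(preprocess, label, segment, filter, emit) on raw text or whole corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import yaml

from .dictionary import SymptomPhrase, annotate_dictionary
from .embedding import EmbeddingSpace, train_embeddings
from .interaction import InteractionModel, InteractionParams
from .position import PositionTable, accumulate_position_counts
from .recognizer import (
    ExtractorConfig,
    Extraction,
    FilterConfig,
    TokenizedSentence,
    extract,
    preprocess,
)
from .tokenizers import Tokenizer, whitespace_tokenizer

__all__ = ["ComDModel"]


@dataclass
class ComDModel:
    """Trained composition models plus extraction configuration."""

    stats: PositionTable
    space: EmbeddingSpace
    interaction: InteractionModel
    tokenizer: Tokenizer = whitespace_tokenizer
    config: ExtractorConfig = field(default_factory=ExtractorConfig)
    filters: Optional[FilterConfig] = None

    @classmethod
    def train(
        cls,
        phrases: Sequence[SymptomPhrase],
        *,
        params: Optional[InteractionParams] = None,
        d: int = 500,
        window: int = 5,
        epochs: int = 10,
        min_count: int = 1,
        seed: int = 0,
        supplementary: Optional[Sequence[Sequence[str]]] = None,
        tokenizer: Tokenizer = whitespace_tokenizer,
        config: Optional[ExtractorConfig] = None,
    ) -> "ComDModel":
        """Train position and interaction models on a symptom dictionary.

        ``supplementary`` optionally adds unlabeled corpus sentences (token
        lists) to embedding training only; the position model always comes
        from the dictionary alone.
        """
        stats = accumulate_position_counts(annotate_dictionary(phrases))
        space = train_embeddings(
            phrases, d=d, window=window, seed=seed,
            epochs=epochs, min_count=min_count, supplementary=supplementary,
        )
        if params is None:
            params = InteractionParams.scaled(len(space), seed=seed)
        interaction = InteractionModel(space, params)
        model = cls(
            stats=stats,
            space=space,
            interaction=interaction,
            tokenizer=tokenizer,
            config=config or ExtractorConfig(),
        )
        model.filters = FilterConfig(known_vocabulary=model.known_vocabulary())
        return model

    def known_vocabulary(self) -> frozenset:
        """Tokens with position statistics or an embedding."""
        return frozenset(self.stats) | frozenset(self.space.index)

    # ------------------------------------------------------------ extraction
    def extract_sentence(
        self,
        sentence: TokenizedSentence,
        config: Optional[ExtractorConfig] = None,
    ) -> List[Extraction]:
        return extract(sentence, self.stats, self.interaction, config or self.config)

    def extract_text(
        self,
        text: str,
        record_id: str = "",
        config: Optional[ExtractorConfig] = None,
        filters: Optional[FilterConfig] = None,
    ) -> List[Extraction]:
        """Run the full pipeline on one free-text record."""
        out: List[Extraction] = []
        for sentence in preprocess(
            text,
            tokenizer=self.tokenizer,
            filters=filters if filters is not None else self.filters,
            record_id=record_id,
        ):
            out.extend(self.extract_sentence(sentence, config))
        return out

    def extract_corpus(
        self,
        records: Dict[str, str],
        config: Optional[ExtractorConfig] = None,
    ) -> Dict[str, List[Extraction]]:
        """Extract from a mapping record id -> text."""
        return {
            rid: self.extract_text(text, record_id=rid, config=config)
            for rid, text in records.items()
        }

    # ------------------------------------------------------------------- I/O
    def save(self, directory: Union[str, Path]) -> None:
        """Persist the model to a directory of plain-text files.

        The interaction model is stored as its embedding matrix plus
        parameters and refit deterministically on load; cluster and
        neighbourhood tables are also written for inspection.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.stats.save(directory / "stats.tsv")
        self.space.save(directory / "embeddings.txt")
        self.interaction.save(directory)
        p = self.interaction.params
        meta = {
            "interaction": {
                "nu": p.nu, "gamma": p.gamma, "n_clusters": p.n_clusters,
                "n_neighbors": p.n_neighbors, "seed": p.seed,
            },
            "extractor": {
                "mode": self.config.mode,
                "delta": self.config.delta,
                "min_segment_score": self.config.min_segment_score,
                "joiner": self.config.joiner,
            },
        }
        (directory / "params.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(
        cls, directory: Union[str, Path], tokenizer: Tokenizer = whitespace_tokenizer
    ) -> "ComDModel":
        directory = Path(directory)
        meta = yaml.safe_load((directory / "params.yaml").read_text())
        stats = PositionTable.load(directory / "stats.tsv")
        space = EmbeddingSpace.load(directory / "embeddings.txt")
        params = InteractionParams(**meta["interaction"])
        interaction = InteractionModel(space, params)
        config = ExtractorConfig(**meta["extractor"])
        model = cls(
            stats=stats, space=space, interaction=interaction,
            tokenizer=tokenizer, config=config,
        )
        model.filters = FilterConfig(known_vocabulary=model.known_vocabulary())
        return model
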