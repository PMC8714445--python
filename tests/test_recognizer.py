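"""Preprocessing, label assignment, segmentation and extraction."""

import itertools

import numpy as np
import pytest

from comd import (
    ExtractorConfig,
    FilterConfig,
    Label,
    PositionStats,
    PositionTable,
    TokenizedSentence,
    assign_labels,
    enumerate_segmentations,
    extract,
    normalize_boundaries,
    preprocess,
    score_segmentation,
    utility,
)
from comd.recognizer import CandidateSegmentation, Segment, candidate_segments

from bruteforce import brute_force_extract, candidate_sets


def make_stats(**counts) -> PositionTable:
    table = PositionTable()
    for comp, c in counts.items():
        table[comp] = PositionStats(component=comp, counts=tuple(c))
    return table


def sentence(*tokens, kept=None, rid="s"):
    return TokenizedSentence(
        record_id=rid, tokens=tokens, kept=kept or (True,) * len(tokens)
    )


class TestPreprocess:
    def test_splits_on_terminators(self):
        sentences = preprocess("a b. c d!", tokenizer=str.split,
                               terminators=frozenset(".!"))
        assert len(sentences) == 2
        assert sentences[0].tokens == ("a", "b")
        assert sentences[1].tokens == ("c", "d")

    def test_cjk_terminators_by_default(self):
        sentences = preprocess("a。b！c", tokenizer=str.split)
        assert [s.tokens for s in sentences] == [("a",), ("b",), ("c",)]

    def test_empty_text_gives_no_sentences(self):
        assert preprocess("") == []

    def test_filters_mark_tokens_not_kept(self):
        filters = FilterConfig(known_vocabulary=frozenset({"a", "b"}), common=frozenset({"b"}))
        (s,) = preprocess("a b zz", tokenizer=str.split, filters=filters)
        assert s.kept == (True, False, False)


class TestFilterConfig:
    def test_from_corpus_common_and_rare(self):
        # 't' tops document frequency; 'once' occurs a single time
        texts = [f"t u{i}" for i in range(10)] + ["t once shared shared"]
        filters = FilterConfig.from_corpus(
            texts, tokenizer=str.split, common_top_fraction=0.1, rare_min_count=2
        )
        assert "t" in filters.common
        assert "once" in filters.rare
        assert filters.keeps("shared")
        assert not filters.keeps("t")
        assert not filters.keeps("once")


class TestAssignLabels:
    def test_nonzero_positions_only(self):
        stats = make_stats(w=(60, 12, 0, 0))
        (cands,) = [assign_labels(sentence("w"), stats).sets[0]]
        assert cands == frozenset({Label.B, Label.I, Label.O})

    def test_pure_single(self):
        stats = make_stats(w=(0, 0, 0, 5))
        cands = assign_labels(sentence("w"), stats).sets[0]
        assert cands == frozenset({Label.S, Label.O})

    def test_filtered_token_with_embedding_is_filler_intermediate(
        self, clustered_interaction
    ):
        stats = make_stats(b=(1, 0, 0, 0), e=(0, 0, 1, 0))
        s = sentence("b", "a0", "e", kept=(True, False, True))
        cands = assign_labels(s, stats, clustered_interaction)
        assert cands.sets[1] == frozenset({Label.I, Label.O})

    def test_unknown_token_is_o_only(self):
        cands = assign_labels(sentence("ghost"), make_stats())
        assert cands.sets[0] == frozenset({Label.O})


class TestEnumeration:
    def test_all_o_single_segmentation(self):
        cands = assign_labels(sentence("ghost", "ghost"), make_stats())
        segs = enumerate_segmentations(cands, make_stats())
        assert len(segs) == 1 and segs[0].q == 0

    def test_single_s_token_two_candidates(self):
        stats = make_stats(w=(0, 0, 0, 1))
        segs = enumerate_segmentations(assign_labels(sentence("w"), stats), stats)
        assert sorted(s.q for s in segs) == [0, 1]

    def test_b_i_e_matches_product_oracle_segment_sets(self):
        """Segment sets agree with a brute-force filter over label products."""
        stats = make_stats(b=(1, 1, 0, 0), m=(0, 1, 0, 0), e=(0, 1, 1, 0))
        s = sentence("b", "m", "e")
        cands = assign_labels(s, stats)
        segs = enumerate_segmentations(cands, stats)
        got = {tuple((x.start, x.end) for x in seg.segments) for seg in segs}

        import re

        valid = re.compile(r"(?:O|S|B+[IO]*E+)*")
        expected = set()
        for labels in itertools.product(*candidate_sets(s, stats, None)):
            labeling = "".join(labels)
            if valid.fullmatch(labeling):
                spans = [
                    m.span() for m in re.finditer(r"B+[IO]*E+|S", labeling)
                ]
                expected.add(tuple(spans))
        assert got == expected

    def test_beam_at_full_width_equals_exhaustive(self):
        stats = make_stats(
            a=(2, 1, 1, 1), b=(1, 2, 1, 1), c=(1, 1, 2, 1), d=(1, 1, 1, 2)
        )
        s = sentence("a", "b", "c", "d")
        cands = assign_labels(s, stats)
        full = enumerate_segmentations(cands, stats)
        beam = enumerate_segmentations(cands, stats, beam_width=len(full))
        assert [f.segments for f in full] == [b.segments for b in beam]

    def test_min_segment_score_floor_prunes(self):
        stats = make_stats(w=(0, 0, 0, 10), v=(0, 0, 0, 1))
        # pi_S = 1.0 for both; floor above 1 removes all segments
        cands = assign_labels(sentence("w", "v"), stats)
        assert candidate_segments(cands, stats, min_segment_score=1.5) == []


class TestScoring:
    def test_segment_score_definitions(self):
        stats = make_stats(s1=(0, 0, 0, 10), b1=(8, 0, 0, 2), e1=(5, 0, 5, 0))
        s = sentence("s1", "b1", "x", "e1")
        single = CandidateSegmentation(
            sentence=s, segments=(Segment(0, 1),),
            labels=(Label.S, Label.O, Label.O, Label.O),
        )
        span = CandidateSegmentation(
            sentence=s, segments=(Segment(1, 4),),
            labels=(Label.O, Label.B, Label.O, Label.E),
        )
        both = CandidateSegmentation(
            sentence=s, segments=(Segment(0, 1), Segment(1, 4)),
            labels=(Label.S, Label.B, Label.O, Label.E),
        )
        assert score_segmentation(single, stats) == pytest.approx(1.0)
        assert score_segmentation(span, stats) == pytest.approx(0.8 * 0.5)
        assert score_segmentation(both, stats) == pytest.approx(1.4)


class TestNormalization:
    def _seg(self, *labels):
        s = sentence(*[f"t{i}" for i in range(len(labels))])
        return CandidateSegmentation(sentence=s, segments=(), labels=labels)

    def test_consecutive_b_collapses_to_leftmost(self):
        out = normalize_boundaries(self._seg(Label.B, Label.B, Label.E))
        assert out.segments == (Segment(0, 3),)
        assert out.labels == (Label.B, Label.I, Label.E)

    def test_consecutive_e_collapses_to_rightmost(self):
        out = normalize_boundaries(self._seg(Label.B, Label.E, Label.E))
        assert out.segments == (Segment(0, 3),)
        assert out.labels == (Label.B, Label.I, Label.E)

    def test_well_formed_span_unchanged(self):
        out = normalize_boundaries(self._seg(Label.B, Label.I, Label.E))
        assert out.labels == (Label.B, Label.I, Label.E)
        assert out.segments == (Segment(0, 3),)

    def test_unclosed_span_rejected(self):
        with pytest.raises(ValueError):
            normalize_boundaries(self._seg(Label.B, Label.I))

    def test_dangling_intermediate_rejected(self):
        with pytest.raises(ValueError):
            normalize_boundaries(self._seg(Label.I, Label.O))


class TestUtilityFiltering:
    def test_utility_is_the_mean_interaction(self, clustered_interaction):
        # within-community scores are 1, cross-community exp(-7.5 ln2)
        value = utility("a0", "b0", "a1", clustered_interaction)
        cross = clustered_interaction.score("a0", "b0")
        assert value == pytest.approx(0.5 * (cross + cross))
        assert utility("a0", "a2", "a1", clustered_interaction) == pytest.approx(1.0)

    def test_span_drops_low_utility_interiors(self, clustered_interaction):
        """B-I-I-I-E keeps the community-mate interior, drops the two
        foreign fillers (utility below delta = 0.5)."""
        stats = make_stats(a0=(5, 0, 0, 0), a2=(0, 5, 0, 0), a1=(0, 0, 5, 0))
        s = sentence("a0", "b0", "a2", "b1", "a1")
        (ex,) = extract(s, stats, clustered_interaction,
                        ExtractorConfig(delta=0.5, joiner=" "))
        assert ex.phrase == "a0 a2 a1"
        assert ex.component_indices == (0, 2, 4)
        assert ex.source_span == (0, 5)

    def test_direct_b_e_span_keeps_both(self, clustered_interaction):
        stats = make_stats(a0=(5, 0, 0, 0), a1=(0, 0, 5, 0))
        (ex,) = extract(sentence("a0", "a1"), stats, clustered_interaction,
                        ExtractorConfig(joiner=" "))
        assert ex.phrase == "a0 a1"

    def test_raising_delta_never_adds_interiors(self, synthetic_world):
        data, model = synthetic_world
        kept_counts = []
        for delta in (0.0, 0.2, 0.5, 0.9):
            config = ExtractorConfig(delta=delta)
            total = sum(
                len(e.component_indices)
                for exs in model.extract_corpus(data.corpus_texts, config=config).values()
                for e in exs
            )
            kept_counts.append(total)
        assert all(a >= b for a, b in zip(kept_counts, kept_counts[1:]))

    def test_delta_zero_equals_no_interaction_mode(self, synthetic_world):
        data, model = synthetic_world
        full0 = model.extract_corpus(data.corpus_texts, config=ExtractorConfig(delta=0.0))
        noint = model.extract_corpus(
            data.corpus_texts, config=ExtractorConfig(mode="no-interaction")
        )
        assert full0 == noint


class TestExtract:
    def test_dictionary_phrase_extracted_verbatim(self, noise_free_world):
        data, model = noise_free_world
        phrase = next(p for p in data.phrases if len(p) >= 2)
        text = " ".join(phrase.components)
        (ex,) = model.extract_text(text, record_id="r")
        assert ex.phrase == "".join(phrase.components)

    def test_empty_sentence_returns_nothing(self, synthetic_world):
        _, model = synthetic_world
        assert model.extract_text("") == []

    def test_extractions_never_overlap_and_are_deterministic(self, synthetic_world):
        data, model = synthetic_world
        first = model.extract_corpus(data.corpus_texts)
        second = model.extract_corpus(data.corpus_texts)
        assert first == second
        for exs in first.values():
            spans = sorted(e.source_span for e in exs)
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_matches_bruteforce_oracle_on_random_sentences(self, synthetic_world):
        """Spot-check of the exhaustive-oracle equivalence on 40 sentences."""
        data, model = synthetic_world
        rng = np.random.default_rng(123)
        vocab = sorted(model.known_vocabulary())
        config = ExtractorConfig(delta=0.2)
        for i in range(40):
            n = int(rng.integers(1, 9))
            tokens = tuple(vocab[j] for j in rng.integers(0, len(vocab), n))
            s = TokenizedSentence(record_id=f"x{i}", tokens=tokens,
                                  kept=(True,) * n)
            assert extract(s, model.stats, model.interaction, config) == \
                brute_force_extract(s, model.stats, model.interaction, config)

    def test_no_position_mode_groups_by_interaction(self, clustered_interaction):
        s = sentence("a0", "b0", "a1", "b1")
        out = extract(s, None, clustered_interaction,
                      ExtractorConfig(mode="no-position", delta=0.5, joiner=" "))
        assert [e.phrase for e in out] == ["a0 a1", "b0 b1"]

    def test_no_position_mode_needs_interaction_model(self):
        with pytest.raises(ValueError):
            extract(sentence("a"), None, None, ExtractorConfig(mode="no-position"))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ExtractorConfig(mode="turbo")
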