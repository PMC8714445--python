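"""Desk-scale synthetic benchmarks.

Repeatable experiments on the synthetic study: train the recognizer on a
generated dictionary, extract from the generated noisy corpus, and score
against the generated gold — across modes (full / no-interaction /
no-position) and seeds.  These are the package's substitutes for
experiments on real consultation data, sized so a full paired-seed sweep
runs in well under a minute per handful of seeds.

The default study conditions: 3 topical component groups (4 begin + 4
interior + 4 end + 2 single each), 12 colloquial fillers, a 300-phrase
dictionary, 100 corpus sentences with 1-2 recombined (position-legal but
possibly unseen) symptom spans, filler insertion rate 0.3, and a fifth of
sentences as pure filler chatter.  Models: 32-dimensional skip-gram
embeddings (window 3, 12 epochs) over dictionary plus corpus, C=6 clusters,
k=10 neighbours, nu=7.5, gamma=0, delta=0.2.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dictionary import annotate_dictionary
from .embedding import train_embeddings
from .evaluation import EvalConfig, EvalReport, evaluate
from .interaction import InteractionModel, InteractionParams
from .pipeline import ComDModel
from .position import accumulate_position_counts
from .recognizer import ExtractorConfig
from .simulate import GeneratorConfig, SyntheticData, generate, generate_dictionary

__all__ = [
    "study_config",
    "train_study_model",
    "mode_reports",
    "ablation_f1",
    "recovery_max_error",
    "interaction_sanity_rate",
    "noise_free_micro_f1",
]

MODES = ("full", "no-interaction", "no-position")


def study_config(seed: int, **overrides) -> GeneratorConfig:
    """The default noisy benchmark conditions for one seed."""
    return GeneratorConfig(seed=seed, **overrides)


def train_study_model(data: SyntheticData, seed: int) -> ComDModel:
    """Train the desk-scale recognizer on a synthetic study."""
    return ComDModel.train(
        data.phrases,
        d=32,
        window=3,
        epochs=12,
        seed=seed,
        supplementary=[toks for _, toks in data.sentences],
        params=InteractionParams(n_clusters=6, n_neighbors=10, seed=seed),
    )


def mode_reports(
    data: SyntheticData,
    model: ComDModel,
    epsilon: float = 0.6,
    delta: float = 0.2,
) -> Dict[str, EvalReport]:
    """Evaluate all three extraction modes on one study."""
    reports = {}
    for mode in MODES:
        config = ExtractorConfig(mode=mode, delta=delta)
        preds = {
            rid: [e.phrase for e in exs]
            for rid, exs in model.extract_corpus(data.corpus_texts, config=config).items()
        }
        reports[mode] = evaluate(preds, data.gold, EvalConfig(epsilon=epsilon))
    return reports


def ablation_f1(
    seeds: Sequence[int], epsilon: float = 0.6, delta: float = 0.2
) -> Dict[str, List[float]]:
    """Paired micro-F1 per mode over seeds (one trained model per seed)."""
    results: Dict[str, List[float]] = {mode: [] for mode in MODES}
    for seed in seeds:
        data = generate(study_config(seed))
        model = train_study_model(data, seed)
        for mode, report in mode_reports(data, model, epsilon, delta).items():
            results[mode].append(report.micro_f1)
    return results


def recovery_max_error(seed: int, n_phrases: int = 10_000) -> float:
    """Max absolute error of estimated vs generating position multinomials."""
    config = study_config(seed, n_phrases=n_phrases, role_purity=0.8)
    phrases, truth = generate_dictionary(config)
    table = accumulate_position_counts(annotate_dictionary(phrases))
    return max(
        abs(est - true)
        for comp, stats in table.items()
        for est, true in zip(stats.probs, truth[comp])
    )


def interaction_sanity_rate(
    seeds: Sequence[int], pairs_per_seed: int = 30
) -> float:
    """Fraction of sampled comparisons where a co-trained (same-group) pair
    scores higher interaction than a cross-group pair.

    Only components that occur in multi-component phrases are sampled:
    single-role components never share a skip-gram context with anything,
    so they are not co-trained and carry no neighbourhood signal.
    """
    wins = 0
    total = 0
    for seed in seeds:
        data = generate(study_config(seed))
        space = train_embeddings(
            data.phrases, d=32, window=3, seed=seed, epochs=12
        )
        model = InteractionModel(
            space, InteractionParams(n_clusters=6, n_neighbors=10, seed=seed)
        )
        by_group: Dict[int, List[str]] = {}
        for comp, g in data.group_of.items():
            if comp in model and data.truth[comp][3] < 1.0:
                by_group.setdefault(g, []).append(comp)
        groups = sorted(by_group)
        rng = np.random.default_rng(seed)
        for _ in range(pairs_per_seed):
            g1, g2 = rng.choice(groups, size=2, replace=False)
            a, b = rng.choice(by_group[g1], size=2, replace=False)
            c = rng.choice(by_group[g2])
            within = model.score(a, b)
            cross = model.score(a, c)
            wins += within > cross
            total += 1
    return wins / total


def noise_free_micro_f1(seed: int) -> float:
    """Micro-F1 at IoU 1.0 on a noise-free study (verbatim spans, no fillers)."""
    config = study_config(
        seed,
        filler_rate=0.0,
        recombine=False,
        filler_sentence_fraction=0.0,
        n_fillers=0,
    )
    data = generate(config)
    model = train_study_model(data, seed)
    (report,) = [mode_reports(data, model, epsilon=1.0)["full"]]
    return report.micro_f1
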