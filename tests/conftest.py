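"""Shared fixtures: a handcrafted two-community embedding world with exact
closed-form interaction scores, and trained models on synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest

from comd import (
    ComDModel,
    EmbeddingSpace,
    InteractionModel,
    InteractionParams,
    GeneratorConfig,
    generate,
)


def two_cluster_model(nu: float = 7.5, gamma: float = 0.0) -> InteractionModel:
    """Two tight, well-separated communities of 6 vectors each.

    Every component's 5 nearest neighbours are its own community, k-means
    with C=2 splits the communities exactly, so neighbourhood distributions
    are point masses: JSD is 0 within a community and ln 2 across.
    """
    rng = np.random.default_rng(42)
    names = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    base = np.zeros((12, 4))
    base[:6, 0] = 1.0
    base[6:, 1] = 1.0
    vectors = base + rng.normal(scale=0.01, size=base.shape)
    space = EmbeddingSpace(index={n: i for i, n in enumerate(names)}, vectors=vectors)
    params = InteractionParams(nu=nu, gamma=gamma, n_clusters=2, n_neighbors=5, seed=0)
    return InteractionModel(space, params)


@pytest.fixture(scope="session")
def clustered_interaction() -> InteractionModel:
    return two_cluster_model()


def train_world(config: GeneratorConfig, **train_overrides):
    """Generate a synthetic study and train a desk-scale model on it."""
    data = generate(config)
    kwargs = dict(
        d=32,
        window=3,
        epochs=12,
        seed=config.seed,
        supplementary=[toks for _, toks in data.sentences],
        params=InteractionParams(n_clusters=6, n_neighbors=10, seed=config.seed),
    )
    kwargs.update(train_overrides)
    model = ComDModel.train(data.phrases, **kwargs)
    return data, model


@pytest.fixture(scope="session")
def synthetic_world():
    """A noisy synthetic study plus a trained model (fixed seed)."""
    return train_world(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_world():
    """Verbatim dictionary spans, no fillers: the lossless recovery setting."""
    config = GeneratorConfig(
        seed=7,
        filler_rate=0.0,
        recombine=False,
        filler_sentence_fraction=0.0,
        n_fillers=0,
    )
    return train_world(config)
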