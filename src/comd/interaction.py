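"""Semantic interaction scores between components.

Two components interact strongly when they occupy similar *neighbourhoods*
of the embedding space, not merely when their vectors are close: the
embedding is first partitioned into C clusters by k-means, each component
is associated with the discrete distribution of its k nearest neighbours'
cluster memberships, and the interaction score between two components is

    I(w_a, w_b) = exp(-nu * JSD(P_a || P_b) + gamma)

where JSD is the Jensen-Shannon divergence between the two neighbourhood
distributions (natural logarithm, so JSD is bounded by ln 2).  With
gamma = 0 the score lies in (exp(-nu ln 2), 1]: 1 for identical
neighbourhoods, small for disjoint ones.  nu scales how sharply the score
decays with divergence.

Plain vector-distance similarities (cosine, Euclidean, Manhattan) are also
provided as baselines for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .embedding import EmbeddingSpace

__all__ = [
    "InteractionParams",
    "NeighborhoodDistribution",
    "InteractionModel",
    "kl_divergence",
    "jsd",
    "interaction_score",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class InteractionParams:
    """Hyper-parameters of the interaction model.

    nu : scaling of the exponential decay (> 0), default 7.5.
    gamma : additive offset inside the exponential, default 0.
    n_clusters : number of k-means clusters C, default 500.
    n_neighbors : neighbourhood size k, default 2000.
    seed : seed for k-means initialisation.

    The defaults suit a dictionary of several hundred thousand phrases;
    ``scaled`` shrinks C and k to a small vocabulary.
    """

    nu: float = 7.5
    gamma: float = 0.0
    n_clusters: int = 500
    n_neighbors: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.n_clusters < 1 or self.n_neighbors < 1:
            raise ValueError("n_clusters and n_neighbors must be >= 1")

    @classmethod
    def scaled(cls, vocab_size: int, **overrides) -> "InteractionParams":
        """Defaults shrunk to a vocabulary: C = min(500, ceil(V/4)),
        k = min(2000, V-1)."""
        params = dict(
            n_clusters=min(500, max(1, -(-vocab_size // 4))),
            n_neighbors=min(2000, max(1, vocab_size - 1)),
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class NeighborhoodDistribution:
    """A component's distribution over embedding clusters.

    Entry c is the fraction of the component's k nearest neighbours
    (cosine distance, query excluded) assigned to cluster c.
    """

    component: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("probs must be a 1-d distribution summing to 1")
        object.__setattr__(self, "probs", p)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(P || Q) with natural log; 0 log 0 terms contribute 0.

    Returns ``inf`` when P places mass where Q has none.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    return float(np.sum(rel_entr(p, q)))


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence: symmetric, finite, in [0, ln 2]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    m = 0.5 * (p + q)
    value = 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)
    # clamp float noise just outside the theoretical range
    return float(min(max(value, 0.0), LN2))


def interaction_score(divergence: float, nu: float = 7.5, gamma: float = 0.0) -> float:
    """exp(-nu * divergence + gamma), capped at 1 when gamma lifts it above."""
    value = math.exp(-nu * divergence + gamma)
    return min(value, 1.0) if gamma > 0 else value


class InteractionModel:
    """Neighbourhood distributions and pairwise interaction scores.

    Fit once on an embedding space; afterwards ``score`` is a cheap lookup
    of two neighbourhood distributions plus a JSD evaluation.
    """

    def __init__(self, space: EmbeddingSpace, params: Optional[InteractionParams] = None):
        if params is None:
            params = InteractionParams.scaled(len(space))
        if params.n_neighbors > len(space) - 1:
            raise ValueError(
                f"k={params.n_neighbors} neighbours requested but vocabulary "
                f"holds only {len(space)} components"
            )
        self.space = space
        self.params = params
        V = len(space)
        C = params.n_clusters
        kmeans = KMeans(n_clusters=C, n_init=10, random_state=params.seed)
        self.cluster_labels = kmeans.fit_predict(space.vectors)
        k = params.n_neighbors
        nn = NearestNeighbors(n_neighbors=min(V, k + 1), metric="cosine")
        nn.fit(space.vectors)
        _, idx = nn.kneighbors(space.vectors)
        # drop the query itself wherever it appears among the neighbours
        self._distributions = np.empty((V, C))
        for i in range(V):
            neigh = idx[i][idx[i] != i][:k]
            occupancy = np.bincount(self.cluster_labels[neigh], minlength=C)
            self._distributions[i] = occupancy / k

    def __contains__(self, component: str) -> bool:
        return component in self.space.index

    def neighborhood_distribution(self, component: str) -> NeighborhoodDistribution:
        try:
            i = self.space.index[component]
        except KeyError:
            raise KeyError(f"component {component!r} is out of vocabulary")
        return NeighborhoodDistribution(component=component, probs=self._distributions[i])

    def divergence(self, a: str, b: str) -> float:
        """JSD between two components' neighbourhood distributions."""
        pa = self.neighborhood_distribution(a).probs
        pb = self.neighborhood_distribution(b).probs
        return jsd(pa, pb)

    def score(self, a: str, b: str) -> float:
        """Interaction score exp(-nu * JSD + gamma), capped at 1."""
        return interaction_score(self.divergence(a, b), self.params.nu, self.params.gamma)

    def baseline_distance_score(self, a: str, b: str, metric: str = "cosine") -> float:
        """Similarity in [0, 1] from a plain vector-distance metric."""
        va, vb = self.space.vector(a), self.space.vector(b)
        if metric == "cosine":
            return 0.5 * (1.0 + self.space.cosine(a, b))
        if metric == "euclidean":
            return math.exp(-self.params.nu * float(np.linalg.norm(va - vb)))
        if metric == "manhattan":
            return math.exp(-self.params.nu * float(np.abs(va - vb).sum()))
        raise ValueError(f"unknown metric {metric!r}")

    # ---------------------------------------------------------------- I/O
    def save(self, directory: Union[str, Path]) -> None:
        """Persist clusters and sparse neighbourhood distributions as TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tokens = list(self.space.index)
        pd.DataFrame(
            {"component": tokens, "cluster": self.cluster_labels}
        ).to_csv(directory / "clusters.tsv", sep="\t", index=False)
        rows = []
        for comp, i in self.space.index.items():
            nz = np.nonzero(self._distributions[i])[0]
            for c in nz:
                rows.append((comp, int(c), self._distributions[i, c]))
        pd.DataFrame(rows, columns=["component", "cluster", "prob"]).to_csv(
            directory / "neighborhoods.tsv", sep="\t", index=False
        )
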