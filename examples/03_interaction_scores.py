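"""Neighbourhood-based interaction scores.

Two tight communities of embedding vectors: within a community every
component's nearest neighbours share one k-means cluster, so the
Jensen-Shannon divergence between neighbourhood distributions is 0 and the
interaction score exp(-nu * JSD) is 1.  Across communities the
distributions are disjoint point masses: JSD = ln 2 and the score drops to
exp(-7.5 ln 2) ~ 0.0055.
"""

import numpy as np

from comd import EmbeddingSpace, InteractionModel, InteractionParams

rng = np.random.default_rng(42)
names = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
base = np.zeros((12, 4))
base[:6, 0] = 1.0   # community A on one axis
base[6:, 1] = 1.0   # community B on another
space = EmbeddingSpace(
    index={n: i for i, n in enumerate(names)},
    vectors=base + rng.normal(scale=0.01, size=base.shape),
)

params = InteractionParams(nu=7.5, gamma=0.0, n_clusters=2, n_neighbors=5, seed=0)
model = InteractionModel(space, params)

print("neighbourhood of a0:", model.neighborhood_distribution("a0").probs)
print("neighbourhood of b0:", model.neighborhood_distribution("b0").probs)
print(f"JSD(a0, a1) = {model.divergence('a0', 'a1'):.4f}"
      f"   -> interaction {model.score('a0', 'a1'):.4f}")
print(f"JSD(a0, b0) = {model.divergence('a0', 'b0'):.4f}"
      f"   -> interaction {model.score('a0', 'b0'):.5f}")
print()
print("cosine baseline for comparison:",
      f"a0-a1 {model.baseline_distance_score('a0', 'a1', 'cosine'):.3f},",
      f"a0-b0 {model.baseline_distance_score('a0', 'b0', 'cosine'):.3f}")
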