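"""KL / Jensen-Shannon divergences and neighbourhood interaction scores."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import jensenshannon

from comd import InteractionParams, jsd, kl_divergence
from comd.interaction import LN2, interaction_score

from conftest import two_cluster_model

distributions = st.lists(
    st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8
).map(lambda w: np.array(w) / np.sum(w))


def paired(draw_len):
    return st.integers(min_value=2, max_value=8).flatmap(
        lambda n: st.tuples(
            st.lists(st.floats(1e-6, 1.0), min_size=n, max_size=n),
            st.lists(st.floats(1e-6, 1.0), min_size=n, max_size=n),
        ).map(lambda pq: (np.array(pq[0]) / sum(pq[0]), np.array(pq[1]) / sum(pq[1])))
    )


class TestKL:
    def test_identity_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_point_mass(self):
        # 1 * ln(1 / 0.5) = ln 2
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(LN2)

    def test_unsupported_mass_is_infinite(self):
        assert kl_divergence([0.5, 0.5], [1.0, 0.0]) == math.inf

    def test_zero_log_zero_contributes_nothing(self):
        assert kl_divergence([0.0, 1.0], [0.5, 0.5]) == pytest.approx(LN2)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence([1.0], [0.5, 0.5])

    @given(paired(None))
    def test_nonnegative_and_zero_iff_equal(self, pq):
        p, q = pq
        value = kl_divergence(p, q)
        assert value >= 0.0
        if np.allclose(p, q):
            assert value == pytest.approx(0.0, abs=1e-9)


class TestJSD:
    def test_identity_zero_and_disjoint_ln2(self):
        assert jsd([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.0, abs=1e-12)
        assert jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(LN2)

    @given(paired(None))
    def test_symmetric_bounded_and_finite(self, pq):
        p, q = pq
        value = jsd(p, q)
        assert value == pytest.approx(jsd(q, p), abs=1e-12)
        assert 0.0 <= value <= LN2
        assert math.isfinite(value)

    @given(paired(None))
    def test_matches_scipy_jensenshannon(self, pq):
        p, q = pq
        assert jsd(p, q) == pytest.approx(jensenshannon(p, q, base=math.e) ** 2, abs=1e-9)

    @given(paired(None))
    def test_invariant_to_joint_cluster_relabeling(self, pq):
        """Relabeling cluster indices permutes both distributions alike and
        leaves the divergence unchanged."""
        p, q = pq
        perm = np.random.RandomState(0).permutation(len(p))
        assert jsd(p[perm], q[perm]) == pytest.approx(jsd(p, q), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            jsd([1.0], [0.5, 0.5])


class TestInteractionScore:
    def test_unit_score_at_zero_divergence(self):
        assert interaction_score(0.0, nu=7.5, gamma=0.0) == 1.0

    def test_score_at_maximal_divergence(self):
        assert interaction_score(LN2, nu=7.5) == pytest.approx(0.00552, abs=5e-5)

    def test_strictly_decreasing_in_divergence(self):
        grid = np.linspace(0.0, LN2, 25)
        scores = [interaction_score(x, nu=7.5) for x in grid]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_positive_gamma_is_capped_at_one(self):
        assert interaction_score(0.0, nu=7.5, gamma=0.3) == 1.0

    def test_equals_exp_gamma_at_zero_divergence(self):
        assert interaction_score(0.0, nu=7.5, gamma=-0.2) == pytest.approx(math.exp(-0.2))


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            InteractionParams(nu=0.0)
        with pytest.raises(ValueError):
            InteractionParams(n_clusters=0)

    def test_scaled_defaults_shrink_with_vocabulary(self):
        params = InteractionParams.scaled(40)
        assert params.n_clusters == 10
        assert params.n_neighbors == 39
        big = InteractionParams.scaled(10**6)
        assert (big.n_clusters, big.n_neighbors) == (500, 2000)


class TestNeighborhoodModel:
    def test_point_mass_distributions_in_separated_communities(self, clustered_interaction):
        dist = clustered_interaction.neighborhood_distribution("a0")
        assert dist.probs.shape == (2,)
        assert sorted(dist.probs) == [0.0, 1.0]

    def test_distributions_sum_to_one(self, clustered_interaction):
        for comp in clustered_interaction.space.index:
            assert clustered_interaction.neighborhood_distribution(
                comp
            ).probs.sum() == pytest.approx(1.0)

    def test_within_community_score_is_one(self, clustered_interaction):
        assert clustered_interaction.score("a0", "a1") == pytest.approx(1.0)

    def test_cross_community_score_matches_closed_form(self, clustered_interaction):
        assert clustered_interaction.score("a0", "b0") == pytest.approx(
            math.exp(-7.5 * LN2), rel=1e-9
        )

    def test_score_is_symmetric(self, clustered_interaction):
        assert clustered_interaction.score("a2", "b3") == pytest.approx(
            clustered_interaction.score("b3", "a2")
        )

    def test_oov_component_raises(self, clustered_interaction):
        with pytest.raises(KeyError):
            clustered_interaction.neighborhood_distribution("ghost")

    def test_k_larger_than_vocabulary_rejected(self, clustered_interaction):
        from comd.interaction import InteractionModel

        with pytest.raises(ValueError):
            InteractionModel(
                clustered_interaction.space,
                InteractionParams(n_clusters=2, n_neighbors=50),
            )


class TestBaselineDistances:
    def test_identical_vectors(self, clustered_interaction):
        assert clustered_interaction.baseline_distance_score(
            "a0", "a0", "cosine"
        ) == pytest.approx(1.0)
        assert clustered_interaction.baseline_distance_score(
            "a0", "a0", "euclidean"
        ) == pytest.approx(1.0)

    def test_orthogonal_vectors_cosine_half(self):
        model = two_cluster_model()
        # communities sit on orthogonal axes up to jitter
        assert model.baseline_distance_score("a0", "b0", "cosine") == pytest.approx(
            0.5, abs=0.02
        )

    def test_unknown_metric_rejected(self, clustered_interaction):
        with pytest.raises(ValueError):
            clustered_interaction.baseline_distance_score("a0", "a1", "chebyshev")
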