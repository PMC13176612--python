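import numpy as np
import pytest

from oracles import gmm_nll_direct, zinb_loss_direct, zinb_pmf_direct
from sccluster import (
    GMMState,
    Partition,
    gmm_nll,
    init_gmm,
    soft_assign,
    zinb_loss,
    zinb_pmf,
)
from sccluster.zinb import nb_log_pmf


class TestZINBPmf:
    def test_no_inflation_equals_nb(self):
        for k in range(6):
            nb = np.exp(nb_log_pmf(k, 2.0, 1.5))
            assert zinb_pmf(k, 0.0, 2.0, 1.5) == pytest.approx(float(nb), rel=1e-12)

    def test_hand_derived_zero_case(self):
        # NB(0|1,1) = 0.5; pmf = 0.5 + 0.5*0.5 = 0.75; -log = 0.28768
        assert zinb_pmf(0, 0.5, 1.0, 1.0) == pytest.approx(0.75, abs=1e-10)
        assert -np.log(zinb_pmf(0, 0.5, 1.0, 1.0)) == pytest.approx(0.28768, abs=1e-5)

    def test_degenerate_dropout(self):
        assert zinb_pmf(0, 1.0, 1.0, 1.0) == pytest.approx(1.0)
        assert zinb_pmf(3, 1.0, 1.0, 1.0) == pytest.approx(0.0)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            zinb_pmf(0, -0.1, 1.0, 1.0)
        with pytest.raises(ValueError):
            zinb_pmf(0, 0.5, -1.0, 1.0)
        with pytest.raises(ValueError):
            zinb_pmf(-1, 0.5, 1.0, 1.0)

    @pytest.mark.parametrize("mu,theta,pi", [(1.0, 1.0, 0.3), (5.0, 2.0, 0.0),
                                             (20.0, 10.0, 0.7), (50.0, 0.5, 0.5)])
    def test_normalizes_to_one(self, mu, theta, pi):
        ks = np.arange(0, 3000)
        total = np.sum(zinb_pmf(ks, pi, mu, theta))
        assert total >= 1.0 - 1e-6


class TestZINBLoss:
    def test_all_dropout_zero_counts(self):
        x = np.zeros((3, 4))
        assert zinb_loss(x, np.ones_like(x), np.ones_like(x), np.ones_like(x)) == 0.0

    def test_single_entry_value(self):
        x = np.array([[0.0]])
        loss = zinb_loss(x, np.array([[0.5]]), np.array([[1.0]]), np.array([[1.0]]))
        assert loss == pytest.approx(0.28768, abs=1e-5)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            x = rng.integers(0, 10, size=(5, 4)).astype(float)
            pi = rng.uniform(0.05, 0.95, size=(5, 4))
            mu = rng.uniform(0.2, 8.0, size=(5, 4))
            theta = rng.uniform(0.3, 5.0, size=(5, 4))
            got = zinb_loss(x, pi, mu, theta)
            expected = zinb_loss_direct(x, pi, mu, theta)
            assert got == pytest.approx(expected, abs=1e-8 * max(1, abs(expected)))

    def test_non_finite_params_raise(self):
        x = np.zeros((1, 1))
        with pytest.raises(ValueError):
            zinb_loss(x, np.array([[np.nan]]), np.ones((1, 1)), np.ones((1, 1)))


class TestGMMNll:
    def test_standard_normal_at_mean(self):
        state = GMMState(np.array([1.0]), np.zeros((1, 2)), np.ones((1, 2)))
        assert gmm_nll(np.zeros((1, 2)), state) == pytest.approx(np.log(2 * np.pi), abs=1e-5)

    def test_identical_components_collapse(self, rng):
        x = rng.normal(size=(10, 3))
        one = GMMState(np.array([1.0]), np.zeros((1, 3)), np.ones((1, 3)))
        two = GMMState(np.array([0.5, 0.5]), np.zeros((2, 3)), np.ones((2, 3)))
        assert gmm_nll(x, two) == pytest.approx(gmm_nll(x, one), rel=1e-12)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            n, d, k = 6, 3, 2
            x = rng.normal(size=(n, d))
            w = rng.dirichlet(np.ones(k))
            means = rng.normal(size=(k, d))
            variances = rng.uniform(0.5, 2.0, size=(k, d))
            state = GMMState(w, means, variances)
            got = gmm_nll(x, state)
            expected = gmm_nll_direct(x, w, means, variances)
            assert got == pytest.approx(expected, abs=1e-8 * max(1, abs(expected)))

    def test_dimension_mismatch_raises(self):
        state = GMMState(np.array([1.0]), np.zeros((1, 2)), np.ones((1, 2)))
        with pytest.raises(ValueError):
            gmm_nll(np.zeros((1, 3)), state)


class TestSoftAssign:
    def test_point_at_far_component_mean(self):
        state = GMMState(np.array([0.5, 0.5]),
                         np.array([[0.0, 0.0], [50.0, 50.0]]),
                         np.ones((2, 2)))
        r = soft_assign(np.array([[0.0, 0.0]]), state)
        assert r[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_components_give_weights(self, rng):
        w = np.array([0.3, 0.7])
        state = GMMState(w, np.zeros((2, 2)), np.ones((2, 2)))
        r = soft_assign(rng.normal(size=(5, 2)), state)
        np.testing.assert_allclose(r, np.tile(w, (5, 1)), atol=1e-12)

    def test_rows_sum_to_one_even_far_away(self):
        state = GMMState(np.array([0.5, 0.5]),
                         np.array([[0.0, 0.0], [1.0, 1.0]]),
                         np.full((2, 2), 1e-4))
        r = soft_assign(np.array([[1e3, 1e3]]), state)  # extreme underflow regime
        assert np.isfinite(r).all()
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-9)

    def test_hard_labels_invariant_to_weight_rescaling(self, rng):
        """Scaling all mixture weights by a constant (then renormalizing, as
        the simplex demands) leaves responsibilities and argmax unchanged."""
        x = rng.normal(size=(20, 2))
        means = np.array([[0.0, 0.0], [2.0, 2.0]])
        v = np.ones((2, 2))
        w = np.array([0.4, 0.6])
        scaled = 3.7 * w
        a = soft_assign(x, GMMState(w, means, v))
        b = soft_assign(x, GMMState(scaled / scaled.sum(), means, v))
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert np.array_equal(np.argmax(a, axis=1), np.argmax(b, axis=1))

    def test_argmax_tie_breaks_to_lowest_index(self):
        state = GMMState(np.array([0.5, 0.5]),
                         np.array([[-1.0, 0.0], [1.0, 0.0]]),
                         np.ones((2, 2)))
        r = soft_assign(np.array([[0.0, 0.0]]), state)  # equidistant point
        np.testing.assert_allclose(r[0], [0.5, 0.5], atol=1e-12)
        assert np.argmax(r, axis=1)[0] == 0


class TestInitGMM:
    def test_two_point_clusters(self):
        latent = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        p = Partition(np.array([0, 0, 1]))
        state = init_gmm(latent, p, variance_floor=1e-4)
        np.testing.assert_allclose(state.means, [[0, 0], [5, 5]])
        np.testing.assert_allclose(state.variances, 1e-4)
        np.testing.assert_allclose(state.weights, [2 / 3, 1 / 3])

    def test_weights_sum_to_one(self, rng):
        latent = rng.normal(size=(30, 4))
        p = Partition(rng.integers(0, 3, size=30))
        state = init_gmm(latent, p)
        assert state.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_centroids_match_bruteforce(self, rng):
        latent = rng.normal(size=(25, 3))
        labels = rng.integers(0, 4, size=25)
        labels[:4] = [0, 1, 2, 3]  # every cluster populated
        state = init_gmm(latent, Partition(labels.copy()))
        canonical = Partition(labels).labels
        for c in range(4):
            np.testing.assert_allclose(
                state.means[c], latent[canonical == c].mean(axis=0), atol=1e-12
            )
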