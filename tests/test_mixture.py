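import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from profilebin import (
    MixtureParams,
    MultinomialMixtureBinner,
    e_step,
    evaluate_binning,
    fit_em,
    hclust_init,
    log_component_weight,
    m_step,
    observed_loglik,
)
from profilebin.simulate import match_components, simulate_community

from conftest import make_config


def random_instance(rng, n_max=200, p_max=10, k_max=5):
    """A random (counts, params) pair with positive row totals."""
    n = int(rng.integers(2, n_max + 1))
    p = int(rng.integers(2, p_max + 1))
    k = int(rng.integers(1, k_max + 1))
    X = rng.poisson(3.0, size=(n, p))
    X[X.sum(axis=1) == 0, 0] = 1
    pi = rng.dirichlet(np.ones(k))
    A = rng.dirichlet(np.ones(p), size=k)
    return X, MixtureParams(pi, A)


class TestLogComponentWeight:
    def test_pure_profile_with_matching_counts_scores_zero(self):
        assert log_component_weight((3, 0), (1, 0), 1.0) == 0.0

    def test_direct_arithmetic_value(self):
        # log 0.5 + 3 log 0.9, computed independently by direct arithmetic
        got = log_component_weight((3, 0), (0.9, 0.1), 0.5)
        assert got == pytest.approx(-1.009228727533424, abs=1e-12)

    def test_zero_profile_entry_with_reads_gives_minus_inf(self):
        assert log_component_weight((0, 3), (1, 0), 0.5) == -np.inf

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            log_component_weight((0, 0), (0.5, 0.5), 1.0)


class TestEStep:
    def test_single_component_gives_certainty(self, rng):
        X, _ = random_instance(rng, k_max=1)
        params = MixtureParams([1.0], rng.dirichlet(np.ones(X.shape[1]))[None, :])
        q = e_step(X, params)
        assert np.allclose(q, 1.0)

    def test_identical_components_split_evenly(self, rng):
        a = rng.dirichlet(np.ones(4))
        params = MixtureParams([0.5, 0.5], np.vstack([a, a]))
        X = rng.poisson(5.0, size=(20, 4)) + 1
        assert np.allclose(e_step(X, params), 0.5)

    def test_two_component_bayes_value(self):
        # q_1 = 0.5*0.9^3 / (0.5*0.9^3 + 0.5*0.1^3) = 729/730
        params = MixtureParams([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]])
        q = e_step(np.array([[3, 0]]), params)
        assert q[0, 0] == pytest.approx(729 / 730, abs=1e-12)

    def test_matches_exact_rational_bayes_oracle(self, rng):
        """Posteriors agree to 1e-10 with Fraction arithmetic on tiny cases."""
        for _ in range(25):
            p = int(rng.integers(2, 4))
            k = int(rng.integers(1, 4))
            # rational parameters so the oracle is exact
            pi_num = rng.integers(1, 10, size=k)
            A_num = rng.integers(1, 10, size=(k, p))
            pi = pi_num / pi_num.sum()
            A = A_num / A_num.sum(axis=1, keepdims=True)
            X = rng.integers(0, 4, size=(5, p))
            X[X.sum(axis=1) == 0, 0] = 1
            q = e_step(X, MixtureParams(pi, A))
            for i in range(X.shape[0]):
                weights = []
                for kk in range(k):
                    w = Fraction(int(pi_num[kk]), int(pi_num.sum()))
                    for j in range(p):
                        a_frac = Fraction(int(A_num[kk, j]), int(A_num[kk].sum()))
                        w *= a_frac ** int(X[i, j])
                    weights.append(w)
                total = sum(weights)
                for kk in range(k):
                    assert abs(q[i, kk] - float(weights[kk] / total)) < 1e-10

    def test_rows_sum_to_one(self, rng):
        X, params = random_instance(rng)
        q = e_step(X, params)
        assert np.abs(q.sum(axis=1) - 1).max() < 1e-10


class TestMStep:
    def test_hard_assignment_pools_column_sums(self, rng):
        X = rng.poisson(4.0, size=(10, 3)) + 1
        q = np.zeros((10, 2))
        q[:, 0] = 1.0
        params = m_step(X, q, smoothing=0)
        assert params.pi[0] == pytest.approx(1.0)
        assert np.allclose(params.A[0], X.sum(axis=0) / X.sum())

    def test_two_point_arithmetic(self):
        X = np.array([[2, 2], [0, 4]])
        q = np.array([[1.0, 0.0], [0.0, 1.0]])
        params = m_step(X, q, smoothing=0)
        assert np.allclose(params.pi, [0.5, 0.5])
        assert np.allclose(params.A, [[0.5, 0.5], [0.0, 1.0]])

    def test_output_always_on_simplex(self, rng):
        for _ in range(20):
            X, params = random_instance(rng, n_max=50)
            q = e_step(X, params)
            out = m_step(X, q)
            assert abs(out.pi.sum() - 1) < 1e-10
            assert np.abs(out.A.sum(axis=1) - 1).max() < 1e-10

    def test_empty_component_is_reseeded_not_nan(self):
        X = np.array([[5, 1], [4, 2], [6, 0]])
        q = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        params = m_step(X, q)
        assert np.isfinite(params.A).all() and np.isfinite(params.pi).all()
        assert params.pi.sum() == pytest.approx(1.0)
        assert (params.A[1] >= 0).all()


class TestObservedLoglik:
    def test_degenerate_single_sample_model_scores_zero(self):
        # with P=1 and a=(1) every count vector has probability 1
        params = MixtureParams([1.0], [[1.0]])
        assert observed_loglik(np.array([[7], [3]]), params) == 0.0

    def test_direct_arithmetic_value(self):
        params = MixtureParams([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]])
        got = observed_loglik(np.array([[3, 0]]), params)
        assert got == pytest.approx(math.log(0.5 * 0.9**3 + 0.5 * 0.1**3), abs=1e-12)

    def test_one_em_iteration_never_decreases_loglik(self, rng):
        for _ in range(50):
            X, params = random_instance(rng, n_max=60)
            before = observed_loglik(X, params)
            after = observed_loglik(X, m_step(X, e_step(X, params)))
            assert after >= before - 1e-8


class TestFitEM:
    def test_trace_is_monotone(self, small_community):
        cm, _ = small_community
        init = hclust_init(cm.counts, 3)
        res = fit_em(cm.counts, init)
        assert (np.diff(res.loglik_trace) >= -1e-8).all()
        assert res.converged

    def test_k1_fit_recovers_pooled_profile(self, small_community):
        cm, _ = small_community
        res = fit_em(cm.counts, hclust_init(cm.counts, 1))
        pooled = cm.counts.sum(axis=0) / cm.counts.sum()
        assert np.abs(res.params.A[0] - pooled).max() < 1e-6

    def test_labels_are_posterior_argmax(self, small_community):
        cm, _ = small_community
        res = fit_em(cm.counts, hclust_init(cm.counts, 3))
        assert (res.labels == np.argmax(res.posterior, axis=1)).all()

    def test_well_separated_simulation_is_recovered(self):
        cm, truth = simulate_community(make_config(3, 10, 500, 250, seed=7))
        res = fit_em(cm.counts, hclust_init(cm.counts, 3))
        assert evaluate_binning(res.labels, truth.labels)["ari"] >= 0.95

    def test_component_permutation_equivariance(self, small_community):
        cm, _ = small_community
        init = hclust_init(cm.counts, 3)
        order = np.array([2, 0, 1])
        a = fit_em(cm.counts, init)
        b = fit_em(cm.counts, init.permuted(order))
        assert a.loglik == pytest.approx(b.loglik, rel=1e-9)
        perm = match_components(b.params.A, a.params.A)
        assert np.abs(b.params.A[perm] - a.params.A).max() < 1e-6

    def test_sample_column_permutation_equivariance(self, small_community):
        cm, _ = small_community
        cols = np.array([3, 1, 0, 2, 7, 5, 6, 4])
        a = fit_em(cm.counts, hclust_init(cm.counts, 3))
        b = fit_em(cm.counts[:, cols], hclust_init(cm.counts[:, cols], 3))
        assert (a.labels == b.labels).all()
        assert np.abs(b.params.A - a.params.A[:, cols]).max() < 1e-8

    def test_k_larger_than_n_is_an_error(self):
        X = np.ones((3, 2), dtype=int)
        init = MixtureParams(np.full(4, 0.25), np.full((4, 2), 0.5))
        with pytest.raises(ValueError, match="exceeds"):
            fit_em(X, init)


class TestEstimatorInterface:
    def test_fitted_attributes_and_shapes(self, small_community):
        cm, _ = small_community
        est = MultinomialMixtureBinner(n_components=3).fit(cm)
        assert est.profiles_.shape == (3, cm.n_samples)
        assert est.weights_.shape == (3,)
        assert est.responsibilities_.shape == (cm.n_contigs, 3)
        assert est.labels_.shape == (cm.n_contigs,)
        assert est.n_components_ == 3

    def test_get_set_params_round_trip(self):
        est = MultinomialMixtureBinner(n_components=4, tol=1e-5)
        params = est.get_params()
        clone = MultinomialMixtureBinner().set_params(**params)
        assert clone.get_params() == params

    def test_predict_matches_training_labels(self, small_community):
        cm, _ = small_community
        est = MultinomialMixtureBinner(n_components=3).fit(cm)
        assert (est.predict(cm.counts) == est.labels_).all()

    def test_fit_rejects_zero_rows(self):
        X = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="filter_contigs"):
            MultinomialMixtureBinner(n_components=1).fit(X)

    @given(st.integers(0, 2**31 - 1))
    def test_parameter_recovery_property(self, seed):
        """Fitted profiles stay close to truth across generator seeds."""
        cm, truth = simulate_community(make_config(3, 12, 300, 300, seed=seed))
        est = MultinomialMixtureBinner(n_components=3).fit(cm)
        order = match_components(est.profiles_, truth.A_true)
        assert np.abs(est.profiles_[order] - truth.A_true).max() < 0.1
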