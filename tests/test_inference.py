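"""Collapsed likelihoods, the partition prior, and the MCMC steps."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from conftest import enumerate_partitions
from plsmix.inference import (
    ChainConfig,
    IMPLSHyperParams,
    MixtureState,
    gibbs_assignment_sweep,
    pls_marginal_loglik,
    pls_posterior_mean,
    posterior_predictive_loglik,
    pyp_partition_logprob,
    run_chains,
    sample_hyperparameters,
    sample_lambda,
)
from plsmix.segmentation import Segmentation, build_design_matrix


def scalar_model():
    """M=1 design with a single 'init' column: C = (1)."""
    return build_design_matrix(Segmentation(((0, 1),)), np.array([0.0]))


def dense_oracle_loglik(X, lam, model, hypers):
    """Stacked-covariance Gaussian density: the profiles of one component
    jointly follow N(0, (1 (x) C) Sigma_mu (1 (x) C)' + lam^-1 I)."""
    X = np.atleast_2d(X)
    n, m = X.shape
    v = model.prior_variances(hypers.v_init, hypers.v_jump, hypers.v_slope)
    T = np.kron(np.ones((n, 1)), model.C)
    cov = T @ np.diag(v) @ T.T + np.eye(n * m) / lam
    return multivariate_normal(mean=np.zeros(n * m), cov=cov).logpdf(X.ravel())


class TestMarginalLoglik:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_matches_dense_oracle(self, n, two_segment_model, small_hypers):
        rng = np.random.default_rng(10 + n)
        X = rng.standard_normal((n, 4))
        lam = float(rng.uniform(0.5, 3.0))
        ours = pls_marginal_loglik(X, lam, two_segment_model, small_hypers)
        oracle = dense_oracle_loglik(X, lam, two_segment_model, small_hypers)
        assert ours == pytest.approx(oracle, rel=1e-11)

    def test_collapsed_prior_limit(self, two_segment_model):
        # as the parameter prior collapses to a point mass at zero, the
        # marginal tends to independent N(0, lam^-1) noise
        hypers = IMPLSHyperParams(v_init=1e-14, v_jump=1e-14, v_slope=1e-14)
        rng = np.random.default_rng(11)
        X = rng.standard_normal((2, 4))
        lam = 2.0
        expected = norm(scale=1 / np.sqrt(lam)).logpdf(X).sum()
        assert pls_marginal_loglik(X, lam, two_segment_model, hypers) == pytest.approx(
            expected, rel=1e-6
        )

    def test_one_dimensional_convolution(self):
        # M=1, C=(1): marginal of a single profile is N(x; 0, v + 1/lam)
        model = scalar_model()
        hypers = IMPLSHyperParams(v_init=2.5)
        x, lam = 0.7, 1.3
        expected = norm(scale=np.sqrt(2.5 + 1 / lam)).logpdf(x)
        assert pls_marginal_loglik([[x]], lam, model, hypers) == pytest.approx(expected)

    def test_invalid_precision_rejected(self, two_segment_model, small_hypers):
        with pytest.raises(ValueError, match="positive"):
            pls_marginal_loglik(np.zeros((1, 4)), 0.0, two_segment_model, small_hypers)


class TestPredictive:
    def test_empty_cluster_one_dimensional(self):
        model = scalar_model()
        hypers = IMPLSHyperParams(v_init=2.5)
        x, lam = -0.4, 0.8
        expected = norm(scale=np.sqrt(2.5 + 1 / lam)).logpdf(x)
        assert posterior_predictive_loglik(
            np.array([x]), None, lam, model, hypers
        ) == pytest.approx(expected)

    @pytest.mark.parametrize("n_k", [1, 3, 5])
    def test_chain_rule_identity(self, n_k, two_segment_model, small_hypers):
        rng = np.random.default_rng(20 + n_k)
        X_k = rng.standard_normal((n_k, 4))
        x = rng.standard_normal(4)
        lam = 1.7
        pred = posterior_predictive_loglik(x, X_k, lam, two_segment_model, small_hypers)
        diff = pls_marginal_loglik(
            np.vstack([X_k, x]), lam, two_segment_model, small_hypers
        ) - pls_marginal_loglik(X_k, lam, two_segment_model, small_hypers)
        assert pred == pytest.approx(diff, rel=1e-10)

    def test_posterior_mean_tends_to_column_space_projection(
        self, two_segment_model, small_hypers
    ):
        rng = np.random.default_rng(21)
        x_star = rng.standard_normal(4)
        X_k = np.tile(x_star, (2000, 1))
        mean = pls_posterior_mean(X_k, 10.0, two_segment_model, small_hypers)
        C = two_segment_model.C
        projection = C @ np.linalg.solve(C.T @ C, C.T @ x_star)
        np.testing.assert_allclose(mean, projection, atol=1e-3)


class TestPartitionPrior:
    def test_single_entity_certain(self):
        assert pyp_partition_logprob([0], alpha=3.0, d=0.2) == pytest.approx(0.0)

    def test_two_entity_seating_rule(self):
        alpha = 1.7
        assert np.exp(pyp_partition_logprob([0, 0], alpha, 0.0)) == pytest.approx(
            1 / (1 + alpha)
        )
        assert np.exp(pyp_partition_logprob([0, 1], alpha, 0.0)) == pytest.approx(
            alpha / (1 + alpha)
        )

    @pytest.mark.parametrize("n", [3, 4, 5])
    @pytest.mark.parametrize("alpha,d", [(1.5, 0.3), (0.7, 0.0), (2.0, 0.9)])
    def test_normalizes_over_all_partitions(self, n, alpha, d):
        total = 0.0
        for partition in enumerate_partitions(list(range(n))):
            labels = np.empty(n, dtype=int)
            for k, block in enumerate(partition):
                labels[block] = k
            total += np.exp(pyp_partition_logprob(labels, alpha, d))
        assert total == pytest.approx(1.0, rel=1e-10)

    @pytest.mark.parametrize("alpha,d", [(0.0, 0.1), (-1.0, 0.0), (1.0, 1.0), (1.0, -0.2)])
    def test_parameter_ranges_enforced(self, alpha, d):
        with pytest.raises(ValueError):
            pyp_partition_logprob([0, 1], alpha, d)


class TestLambdaStep:
    def test_zero_proposal_scale_never_moves(self, two_segment_model, small_hypers):
        rng = np.random.default_rng(30)
        X = rng.standard_normal((4, 4))
        state = MixtureState(X, two_segment_model, small_hypers)
        cid = next(iter(state.clusters))
        before = state.clusters[cid]["lam"]
        config = ChainConfig(n_chains=1, n_iterations=2, n_skip=0, scale_lambda=0.0)
        after = sample_lambda(state, cid, config, rng)
        assert after == before

    def test_flat_likelihood_recovers_gamma_prior_mean(self):
        # with a huge parameter prior variance the collapsed likelihood is
        # nearly flat in lambda, so the MH chain targets ~Gamma(a, b)
        model = scalar_model()
        hypers = IMPLSHyperParams(a=3.0, b=1.5, v_init=1e8)
        state = MixtureState(np.array([[0.0]]), model, hypers)
        cid = next(iter(state.clusters))
        config = ChainConfig(n_chains=1, n_iterations=2, n_skip=0, mh_steps_per_update=1)
        rng = np.random.default_rng(31)
        draws = [sample_lambda(state, cid, config, rng) for _ in range(40_000)]
        mean = np.mean(draws[2000:])
        assert mean == pytest.approx(hypers.a / hypers.b, rel=0.1)


class TestAssignmentSweep:
    def test_vanishing_alpha_never_creates_clusters(self, two_segment_model):
        hypers = IMPLSHyperParams(alpha=1e-12, d=0.0, a=2.0, b=1.0)
        rng = np.random.default_rng(40)
        X = rng.standard_normal((6, 4))
        state = MixtureState(X, two_segment_model, hypers)
        config = ChainConfig(n_chains=1, n_iterations=2, n_skip=0)
        for _ in range(30):
            gibbs_assignment_sweep(state, config, rng)
        assert state.n_clusters == 1

    def test_identical_profiles_co_cluster(self, two_segment_model):
        # two identical profiles under a sharp likelihood sit together in
        # essentially every sweep
        hypers = IMPLSHyperParams(alpha=1.0, d=0.0, a=50.0, b=0.5)
        x = np.array([1.0, 2.0, 0.5, -1.0])
        X = np.vstack([x, x])
        rng = np.random.default_rng(41)
        state = MixtureState(X, two_segment_model, hypers)
        config = ChainConfig(n_chains=1, n_iterations=2, n_skip=0)
        together = 0
        n_sweeps = 400
        for _ in range(n_sweeps):
            for cid in list(state.clusters):
                sample_lambda(state, cid, config, rng)
            gibbs_assignment_sweep(state, config, rng)
            together += state.n_clusters == 1
        assert together / n_sweeps > 0.95

    def test_state_stays_consistent(self, two_segment_model, small_hypers):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((8, 4))
        state = MixtureState(X, two_segment_model, small_hypers)
        config = ChainConfig(n_chains=1, n_iterations=2, n_skip=0)
        for _ in range(20):
            gibbs_assignment_sweep(state, config, rng)
            members = sorted(i for c in state.clusters.values() for i in c["members"])
            assert members == list(range(8))
            assert all(c["n"] == len(c["members"]) for c in state.clusters.values())
            assert state.lam.size == state.n_clusters


class TestHyperStep:
    def test_zero_scales_leave_hypers_unchanged(self, two_segment_model, small_hypers):
        rng = np.random.default_rng(50)
        X = rng.standard_normal((5, 4))
        state = MixtureState(X, two_segment_model, small_hypers)
        config = ChainConfig(
            n_chains=1, n_iterations=2, n_skip=0,
            scale_a=0.0, scale_b=0.0, scale_alpha=0.0, scale_d=0.0,
        )
        out = sample_hyperparameters(state, config, rng)
        # d passes through a logit round-trip, hence the approx comparison
        assert (out.a, out.b, out.alpha) == (
            small_hypers.a, small_hypers.b, small_hypers.alpha,
        )
        assert out.d == pytest.approx(small_hypers.d, rel=1e-12)

    def test_gamma_hypers_track_precisions(self, two_segment_model):
        # many identical precisions: the posterior mean a/b should sit near
        # the common precision value (Gamma mean matching)
        rng = np.random.default_rng(51)
        lam_true = 4.0
        n_clusters = 30
        X = rng.standard_normal((n_clusters, 4))
        hypers = IMPLSHyperParams(alpha=1.0, d=0.01, a=1.0, b=1.0)
        state = MixtureState(
            X, two_segment_model, hypers,
            assignments=np.arange(n_clusters),
            lam=np.full(n_clusters, lam_true),
        )
        config = ChainConfig(n_chains=1, n_iterations=2, n_skip=0, mh_steps_per_update=2)
        ratios = []
        for _ in range(4000):
            out = sample_hyperparameters(state, config, rng)
            ratios.append(out.a / out.b)
        assert np.mean(ratios[500:]) == pytest.approx(lam_true, rel=0.15)


class TestRunChains:
    def test_similarity_invariants_and_determinism(self, two_segment_model, small_hypers):
        rng = np.random.default_rng(60)
        X = rng.standard_normal((5, 4))
        config = ChainConfig(n_chains=2, n_iterations=120, n_skip=20, seed=9)
        sim1, trace1 = run_chains(X, two_segment_model, config, small_hypers)
        sim2, _ = run_chains(X, two_segment_model, config, small_hypers)
        np.testing.assert_array_equal(sim1.values, sim2.values)
        np.testing.assert_array_equal(np.diag(sim1.values), 1.0)
        np.testing.assert_array_equal(sim1.values, sim1.values.T)
        # off-diagonal entries are integer multiples of 1/n_retained
        off = sim1.values[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(
            np.round(off * sim1.n_retained), off * sim1.n_retained, atol=1e-9
        )
        assert sim1.n_retained == 2 * 100
        assert set(trace1.trace.columns) == {"chain", "iteration", "K", "alpha", "d", "a", "b"}
        assert len(trace1.trace) == 2 * 120

    def test_different_seeds_differ(self, two_segment_model, small_hypers):
        rng = np.random.default_rng(61)
        X = rng.standard_normal((4, 4))
        config1 = ChainConfig(n_chains=1, n_iterations=150, n_skip=50, seed=1)
        config2 = ChainConfig(n_chains=1, n_iterations=150, n_skip=50, seed=2)
        sim1, _ = run_chains(X, two_segment_model, config1, small_hypers)
        sim2, _ = run_chains(X, two_segment_model, config2, small_hypers)
        assert not np.array_equal(sim1.values, sim2.values)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iterations=100, n_skip=100)
        with pytest.raises(ValueError):
            ChainConfig(n_chains=0)
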