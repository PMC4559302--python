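import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

import areamix as am
from areamix import (
    COVARIANCE_TYPES,
    FeatureMatrix,
    GaussianMixture,
    GaussianMixtureResults,
    bic,
    e_step,
    fit_em,
    log_likelihood,
    m_step,
    n_parameters,
    select_model,
)
from conftest import separated_mixture_config


def _model(weights, means, covs, covariance_type="full-varying"):
    weights = np.asarray(weights, float)
    means = np.atleast_2d(np.asarray(means, float))
    covs = np.asarray(covs, float)
    k, d = means.shape
    p = n_parameters(k, d, covariance_type)
    return GaussianMixtureResults(
        k=k, weights=weights, means=means, covariances=covs,
        covariance_type=covariance_type, loglik=0.0, n_params=p, n_obs=1,
        bic=0.0, converged=True, n_iter=0)


class TestEStep:
    def test_identical_components_give_uniform_rows(self, rng):
        X = rng.normal(size=(20, 2))
        covs = np.stack([np.eye(2)] * 2)
        model = _model([0.5, 0.5], [[0, 0], [0, 0]], covs)
        resp = e_step(X, model)
        np.testing.assert_allclose(resp, 0.5)

    def test_dominance_at_far_separation(self):
        model = _model([0.5, 0.5], [[0.0], [100.0]],
                       np.ones((2, 1, 1)))
        resp = e_step(np.array([[0.0]]), model)
        np.testing.assert_allclose(resp[0], [1.0, 0.0], atol=1e-10)

    def test_hand_computed_univariate_posterior(self):
        # pi=(.5,.5), mu=(-1,1), sigma=1: at y=0 densities tie; at y=1 the
        # ratio is exp(-2) : 1
        model = _model([0.5, 0.5], [[-1.0], [1.0]], np.ones((2, 1, 1)))
        resp0 = e_step(np.array([[0.0]]), model)
        np.testing.assert_allclose(resp0[0], [0.5, 0.5], atol=1e-12)
        resp1 = e_step(np.array([[1.0]]), model)
        expected = np.array([np.exp(-2.0), 1.0])
        expected /= expected.sum()
        np.testing.assert_allclose(resp1[0], expected, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(50, 3))
        covs = np.stack([np.eye(3), 2 * np.eye(3), 0.5 * np.eye(3)])
        model = _model([0.2, 0.5, 0.3], rng.normal(size=(3, 3)), covs)
        resp = e_step(X, model)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        model = _model([1.0], [[0.0, 0.0]], np.eye(2)[None])
        with pytest.raises(ValueError, match="expects 2"):
            e_step(rng.normal(size=(5, 3)), model)


class TestMStep:
    def test_all_mass_on_first_component_reduces_to_mle(self, rng):
        X = rng.normal(size=(40, 2))
        resp = np.column_stack([np.ones(40), np.zeros(40)])
        with pytest.raises(am.DegenerateComponentError):
            m_step(X, resp)  # second component has no mass
        resp = np.column_stack([np.full(40, 1.0)])
        w, mu, covs, _ = m_step(X, resp)
        np.testing.assert_allclose(w, [1.0])
        np.testing.assert_allclose(mu[0], X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(covs[0], np.cov(X.T, bias=True), atol=1e-12)

    def test_hard_assignment_recovers_per_cloud_means(self, rng):
        a = rng.normal(-5, 1, size=(30, 2))
        b = rng.normal(5, 1, size=(50, 2))
        X = np.vstack([a, b])
        resp = np.zeros((80, 2))
        resp[:30, 0] = 1.0
        resp[30:, 1] = 1.0
        w, mu, _, _ = m_step(X, resp)
        np.testing.assert_allclose(w, [30 / 80, 50 / 80])
        np.testing.assert_allclose(mu[0], a.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(mu[1], b.mean(axis=0), atol=1e-12)

    def test_uniform_responsibilities_collapse_to_grand_mean(self, rng):
        X = rng.normal(size=(60, 3))
        resp = np.full((60, 3), 1 / 3)
        _, mu, _, _ = m_step(X, resp)
        for j in range(3):
            np.testing.assert_allclose(mu[j], X.mean(axis=0), atol=1e-12)

    @pytest.mark.parametrize("cov_type", COVARIANCE_TYPES)
    def test_covariances_positive_definite(self, rng, cov_type):
        X = rng.normal(size=(50, 3))
        resp = rng.uniform(0.05, 1.0, size=(50, 2))
        resp /= resp.sum(axis=1, keepdims=True)
        w, mu, covs, _ = m_step(X, resp, cov_type)
        assert w == pytest.approx(w, abs=0)  # finite
        np.testing.assert_allclose(w.sum(), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(covs).min() > 0


class TestLogLikelihood:
    def test_standard_normal_at_mode(self):
        model = _model([1.0], [[0.0]], np.ones((1, 1, 1)))
        ll = log_likelihood(np.array([[0.0]]), model)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-14)

    def test_duplicated_dataset_doubles_loglik(self, rng):
        X = rng.normal(size=(15, 2))
        covs = np.stack([np.eye(2), np.eye(2)])
        model = _model([0.4, 0.6], [[0, 0], [1, 1]], covs)
        ll = log_likelihood(X, model)
        ll2 = log_likelihood(np.vstack([X, X]), model)
        assert ll2 == pytest.approx(2 * ll, rel=1e-14)

    def test_against_direct_density_summation(self, rng):
        # brute-force oracle: sum the weighted component densities directly
        X = rng.normal(size=(5, 2))
        means = rng.normal(size=(3, 2))
        covs = np.stack([np.eye(2), 2 * np.eye(2),
                         np.array([[2.0, 0.5], [0.5, 1.0]])])
        w = np.array([0.2, 0.3, 0.5])
        model = _model(w, means, covs)
        direct = sum(
            np.log(sum(w[j] * multivariate_normal.pdf(x, means[j], covs[j])
                       for j in range(3)))
            for x in X)
        assert log_likelihood(X, model) == pytest.approx(direct, abs=1e-12)


class TestBic:
    def test_arithmetic(self):
        assert bic(0.0, 2, int(np.e ** 2)) == pytest.approx(
            -2 * np.log(int(np.e ** 2)))
        assert bic(0.0, 2, np.e ** 2) == pytest.approx(-4.0)

    def test_single_gaussian_closed_form(self, rng):
        # K=1, 1-D: lhat = -N/2 (log 2*pi*sigma2_mle + 1), p = 2
        x = rng.normal(3, 2, size=200)
        res = fit_em(x[:, None], 1, "full-varying", seed=0)
        s2 = x.var()  # MLE (1/N)
        lhat = -0.5 * 200 * (np.log(2 * np.pi * s2) + 1)
        assert res.loglik == pytest.approx(lhat, abs=1e-8)
        assert res.n_params == 2
        assert res.bic == pytest.approx(2 * lhat - 2 * np.log(200), abs=1e-8)

    def test_nested_models_gap_is_log_n(self):
        n = 500
        assert (bic(-100.0, 5, n) - bic(-100.0, 4, n)) == pytest.approx(
            -np.log(n), abs=1e-12)

    @pytest.mark.parametrize("cov_type,expected", [
        ("spherical-equal", (3 - 1) + 3 * 4 + 1),
        ("spherical-varying", (3 - 1) + 3 * 4 + 3),
        ("diagonal-equal", (3 - 1) + 3 * 4 + 4),
        ("diagonal-varying", (3 - 1) + 3 * 4 + 12),
        ("full-equal", (3 - 1) + 3 * 4 + 10),
        ("full-varying", (3 - 1) + 3 * 4 + 30),
    ])
    def test_parameter_counts(self, cov_type, expected):
        assert n_parameters(3, 4, cov_type) == expected


class TestFitEm:
    def test_k1_closed_form_single_iteration_family(self, rng):
        X = rng.normal(size=(80, 3))
        res = fit_em(X, 1, "full-varying", seed=0)
        np.testing.assert_allclose(res.means[0], X.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(res.covariances[0],
                                   np.cov(X.T, bias=True), atol=1e-10)
        assert res.loglik == pytest.approx(log_likelihood(X, res), abs=1e-10)

    def test_two_point_masses(self):
        # 100 points at -5 and 100 at +5 (1-D): the separable-components
        # limit; weights and means are recovered almost exactly
        X = np.concatenate([np.full(100, -5.0), np.full(100, 5.0)])[:, None]
        res = fit_em(X, 2, "spherical-varying", seed=0)
        order = np.argsort(res.means[:, 0])
        np.testing.assert_allclose(res.weights[order], [0.5, 0.5], atol=0.01)
        np.testing.assert_allclose(res.means[order, 0], [-5.0, 5.0], atol=0.01)

    def test_bit_identical_under_same_seed(self, rng):
        X = rng.normal(size=(100, 2))
        a = fit_em(X, 3, "diagonal-varying", seed=42)
        b = fit_em(X, 3, "diagonal-varying", seed=42)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.covariances, b.covariances)
        assert a.loglik == b.loglik

    def test_permutation_equivariance(self, rng):
        cfg = separated_mixture_config(seed=2, n_units=150)
        fm, _ = am.generate_mixture(cfg)
        X = fm.values
        perm = rng.permutation(len(X))
        a = fit_em(X, 3, "spherical-varying", seed=1)
        b = fit_em(X[perm], 3, "spherical-varying", seed=1)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)
        assert a.bic == pytest.approx(b.bic, abs=1e-6)
        # labels permute along with the rows (up to component renaming)
        assert am.adjusted_rand(a.predict(X)[perm], b.predict(X[perm])) == 1.0

    def test_loglik_history_non_decreasing(self, rng):
        X = rng.normal(size=(120, 3))
        for cov in COVARIANCE_TYPES:
            res = fit_em(X, 2, cov, seed=7)
            diffs = np.diff(res.loglik_history)
            assert diffs.min() >= -1e-8 * max(1.0, abs(res.loglik))

    def test_warns_on_unstandardized_feature_matrix(self, rng):
        fm = FeatureMatrix(rng.normal(5, 2, size=(50, 2)), ["a", "b"])
        with pytest.warns(UserWarning, match="non-standardized"):
            fit_em(fm, 1, seed=0)

    def test_model_results_api(self, rng):
        X = rng.normal(size=(60, 2))
        res = GaussianMixture(X, k=2, covariance_type="diagonal-equal").fit(seed=3)
        assert res.k == 2
        labels = res.predict(X)
        assert labels.min() >= 1 and labels.max() <= 2
        assert "BIC" in res.summary()


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=10_000),
       st.sampled_from(COVARIANCE_TYPES),
       st.integers(min_value=1, max_value=3))
def test_em_monotone_loglik_property(seed, cov_type, k):
    """EM never decreases the observed-data log-likelihood."""
    r = np.random.default_rng(seed)
    X = r.normal(size=(r.integers(30, 80), r.integers(1, 4)))
    try:
        res = fit_em(X, k, cov_type, seed=seed, n_starts=2)
    except am.FitFailureError:
        return
    diffs = np.diff(res.loglik_history)
    assert diffs.min() >= -1e-8 * max(1.0, abs(res.loglik))


class TestSelectModel:
    def test_k_range_singleton_returns_single_gaussian(self, rng):
        X = rng.normal(size=(80, 2))
        sol = select_model(X, k_range=[1], seed=0)
        assert sol.k == 1
        assert np.all(sol.labels == 1)

    def test_recovers_three_separated_components(self):
        cfg = separated_mixture_config(seed=5)
        fm, truth = am.generate_mixture(cfg)
        sol = select_model(am.standardize(fm.to_dataframe(),
                                          fm.variable_names),
                           k_range=range(1, 7), seed=5)
        assert sol.k == 3
        assert am.adjusted_rand(sol.labels, truth) >= 0.95

    def test_null_data_prefers_one_component(self, rng):
        X = rng.standard_normal((500, 3))
        sol = select_model(X, k_range=range(1, 5), seed=1)
        assert sol.k == 1

    def test_bic_table_covers_grid_and_selected_is_max(self, rng):
        X = rng.normal(size=(100, 2))
        sol = select_model(X, k_range=range(1, 4), seed=2)
        assert sol.bic_table.shape == (3, len(COVARIANCE_TYPES))
        assert sol.model.bic == pytest.approx(np.nanmax(sol.bic_table.values))

    def test_labels_are_argmax_of_responsibilities(self, rng):
        cfg = separated_mixture_config(seed=8, n_units=120)
        fm, _ = am.generate_mixture(cfg)
        sol = select_model(fm.values, k_range=range(1, 5), seed=8)
        np.testing.assert_array_equal(
            sol.labels, np.argmax(sol.responsibilities, axis=1) + 1)

    def test_one_dimensional_families_collapse(self, rng):
        X = rng.normal(size=(100, 1))
        sol = select_model(X, k_range=[1, 2], seed=0)
        t = sol.bic_table
        for kind in ("equal", "varying"):
            cols = [c for c in t.columns if c.endswith(kind)]
            sub = t[cols].to_numpy()
            assert np.all(np.isclose(sub, sub[:, :1], equal_nan=True))


@pytest.mark.parametrize("cov_type", COVARIANCE_TYPES)
def test_compiled_and_numpy_em_paths_agree(rng, cov_type):
    """The compiled EM kernel and the numpy reference path are one algorithm."""
    from areamix.mixture import _em_loop, _em_loop_numpy

    X = np.vstack([rng.normal(-3, 1, (60, 3)), rng.normal(3, 1, (60, 3))])
    resp0 = rng.uniform(0.1, 1.0, (120, 2))
    resp0 /= resp0.sum(axis=1, keepdims=True)
    floor = 1e-6 * X.var(axis=0).mean()
    fast = _em_loop(X, resp0, cov_type, 1e-8, 300, floor)
    ref = _em_loop_numpy(X, resp0, cov_type, 1e-8, 300, floor)
    assert fast[6] == ref[6]  # same iteration count
    assert fast[3] == pytest.approx(ref[3], abs=1e-9)
    np.testing.assert_allclose(fast[1], ref[1], atol=1e-9)
    np.testing.assert_allclose(fast[2], ref[2], atol=1e-9)


def test_reference_implementation_loglik_agreement():
    """Full-covariance EM reaches the same optimum as sklearn on fixed data."""
    from sklearn.mixture import GaussianMixture as SkGM
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(-2, 1, (25, 2)), rng.normal(2, 1, (25, 2))])
    mine = fit_em(X, 2, "full-varying", seed=0, tol=1e-12, max_iter=2000)
    sk = SkGM(2, covariance_type="full", tol=1e-12, reg_covar=0,
              max_iter=2000, n_init=3, random_state=0).fit(X)
    assert mine.loglik == pytest.approx(sk.score(X) * len(X), abs=1e-6)
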