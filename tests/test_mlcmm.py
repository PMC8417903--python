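"""Latent-class mixed model: likelihood, fitting, classification, prediction."""

import numpy as np
import pytest

from oracles import (maximise_single_class, mixture_loglik_quadrature,
                     single_class_loglik_dense, subject_loglik_quadrature)
from trajclust import data_prep, mlcmm, synthetic
from trajclust.cluster_summary import adjusted_rand
from trajclust.mlcmm import MLCMMData, MLCMMParams, MLCMMSpec


def _toy_params(G=2, p=2, seed=0):
    rng = np.random.default_rng(seed)
    return MLCMMParams(
        xi0=np.append(rng.normal(0, 1, G - 1), 0.0),
        beta=rng.normal(0, 0.3, p),
        gamma_int=np.concatenate([[0.0], rng.normal(0, 2, G - 1)]),
        gamma_slope=rng.normal(0, 1, G),
        eta1=np.array([5.0, 80.0]),
        eta2=np.array([0.8, 4.0]),
        sigma=np.array([0.7, 1.5]),
        omega=np.append(np.exp(rng.normal(0, 0.5, G - 1)), 1.0),
    )


def _toy_data(n=12, seed=1, max_visits=3, p=2):
    """Small irregular dataset with missing outcomes, <= 3 visits each."""
    rng = np.random.default_rng(seed)
    ids, X, rows = [], [], []
    for i in range(n):
        ids.append(f"s{i}")
        X.append(rng.normal(0, 1, p))
        times = np.sort(rng.choice([0.0, 0.5, 1.0, 2.0, 3.0],
                                   rng.integers(1, max_visits + 1),
                                   replace=False))
        for t in times:
            for k in (0, 1):
                if rng.random() < 0.8:
                    rows.append((i, t, k, rng.normal([5, 80][k], [1, 5][k])))
    ids = np.array(ids)
    X = np.array(X)
    M = max(sum(1 for r in rows if r[0] == i) for i in range(n))
    y = np.zeros((n, M)); t = np.zeros((n, M))
    k = np.zeros((n, M), int); mask = np.zeros((n, M), bool)
    slot = [0] * n
    for i, tt, kk, yy in rows:
        j = slot[i]
        y[i, j], t[i, j], k[i, j], mask[i, j] = yy, tt, kk, True
        slot[i] += 1
    keep = mask.any(axis=1)
    return MLCMMData(ids[keep], X[keep], y[keep], t[keep], k[keep], mask[keep])


class TestClassProbabilities:
    def test_uniform_and_single(self):
        assert mlcmm.class_probabilities(np.zeros(4)) == pytest.approx([0.25] * 4)
        assert mlcmm.class_probabilities(np.zeros(1)) == pytest.approx([1.0])

    def test_published_membership_logits(self):
        # softmax of (1.30, -1.04, -0.87, 0) with the last class as reference
        probs = mlcmm.class_probabilities(np.array([1.30, -1.04, -0.87, 0.0]))
        assert probs == pytest.approx([0.674, 0.065, 0.077, 0.184], abs=5e-4)
        assert probs.sum() == pytest.approx(1.0)


class TestLatentMean:
    def test_slope_only_and_reference(self):
        params = _toy_params()
        params.beta[:] = 0
        params.gamma_int[:] = 0
        params.gamma_slope[:] = [0.0, 1.0]
        assert mlcmm.latent_mean(params, 1, np.zeros(2), 2.0) == pytest.approx(2.0)
        assert mlcmm.latent_mean(params, 0, np.zeros(2), 0.0) == pytest.approx(0.0)

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError):
            mlcmm.latent_mean(_toy_params(), 0, np.array([1.0, np.nan]), 1.0)


class TestSubjectLoglik:
    def test_matches_quadrature_oracle(self):
        data = _toy_data()
        params = _toy_params()
        for i in range(data.n_subjects):
            for g in range(2):
                ours = mlcmm.subject_class_loglik(params, data, i, g)
                oracle = subject_loglik_quadrature(params, data, i, g)
                assert ours == pytest.approx(oracle, abs=1e-6)

    def test_vanishing_random_effect_univariate_limit(self):
        data = _toy_data(n=3, max_visits=1)
        params = _toy_params()
        params.omega[0] = 1e-14
        params.eta1[:] = 0.0
        params.eta2[:] = 1.0
        i = 0
        mask = data.mask[i]
        y = data.y[i][mask][0]
        kk = data.k[i][mask][0]
        mu = mlcmm.latent_mean(params, 0, data.X[i], data.t[i][mask][0])
        sd = params.sigma[kk]
        expected = -0.5 * np.log(2 * np.pi * sd ** 2) \
            - 0.5 * ((y - mu) / sd) ** 2
        assert mlcmm.subject_class_loglik(params, data, i, 0) == \
            pytest.approx(expected, abs=1e-8)

    def test_link_scale_jacobian_bookkeeping(self):
        # doubling eta2 for one outcome with 3 observations, while moving
        # y so the transformed outcomes are unchanged, costs exactly 3 log 2
        params = _toy_params()
        data = _toy_data(n=1, seed=5)
        i = 0
        mask = data.mask[i]
        n_k0 = int((data.k[i][mask] == 0).sum())
        base = mlcmm.subject_class_loglik(params, data, i, 0)
        params2 = params.copy()
        params2.eta2 = params.eta2 * np.array([2.0, 1.0])
        data2 = MLCMMData(data.subject_ids, data.X,
                          np.where(data.k == 0,
                                   2 * data.y - params.eta1[0], data.y),
                          data.t, data.k, data.mask)
        shifted = mlcmm.subject_class_loglik(params2, data2, i, 0)
        assert shifted == pytest.approx(base - n_k0 * np.log(2.0), abs=1e-9)


class TestLogLikelihood:
    def test_single_subject_single_class(self):
        data = _toy_data(n=1)
        params = _toy_params(G=1)
        assert mlcmm.log_likelihood(params, data) == pytest.approx(
            mlcmm.subject_class_loglik(params, data, 0, 0))

    def test_label_switching_invariance(self):
        data = _toy_data()
        params = _toy_params(G=3)
        perm = [2, 0, 1]
        swapped = params.copy()
        swapped.xi0 = params.xi0[perm]
        swapped.gamma_int = params.gamma_int[perm]
        swapped.gamma_slope = params.gamma_slope[perm]
        swapped.omega = params.omega[perm]
        assert mlcmm.log_likelihood(swapped, data) == pytest.approx(
            mlcmm.log_likelihood(params, data), abs=1e-9)

    def test_matches_quadrature_oracle(self):
        data = _toy_data(n=8, seed=3)
        params = _toy_params()
        assert mlcmm.log_likelihood(params, data) == pytest.approx(
            mixture_loglik_quadrature(params, data), abs=1e-6)

    def test_relabel_classes_is_equivariant(self):
        data = _toy_data()
        spec = MLCMMSpec(n_classes=2, n_covariates=2)
        params = _toy_params()
        relabelled = mlcmm.relabel_classes(params, [1, 0], spec)
        assert relabelled.gamma_int[0] == 0.0
        assert relabelled.omega[-1] == 1.0
        assert mlcmm.log_likelihood(relabelled, data) == pytest.approx(
            mlcmm.log_likelihood(params, data), abs=1e-8)


class TestPosteriorAndAssignment:
    def test_rows_sum_to_one_and_bayes(self):
        data = _toy_data()
        params = _toy_params()
        post = mlcmm.posterior_from_params(params, data)
        assert post.sum(axis=1) == pytest.approx(np.ones(len(post)), abs=1e-10)
        # explicit Bayes ratio for subject 0
        l0 = np.exp(mlcmm.subject_class_loglik(params, data, 0, 0))
        l1 = np.exp(mlcmm.subject_class_loglik(params, data, 0, 1))
        pi = mlcmm.class_probabilities(params.xi0)
        assert post[0, 0] == pytest.approx(
            pi[0] * l0 / (pi[0] * l0 + pi[1] * l1))

    def test_equal_likelihood_returns_prior(self):
        data = _toy_data()
        params = _toy_params()
        params.gamma_int[:] = 0
        params.gamma_slope[:] = params.gamma_slope[0]
        params.omega[:] = 1.0
        post = mlcmm.posterior_from_params(params, data)
        pi = mlcmm.class_probabilities(params.xi0)
        assert np.allclose(post, pi[None, :], atol=1e-10)

    def test_hard_assign_ties_to_lowest_index(self):
        labels = mlcmm.hard_assign(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert labels.tolist() == [0, 1]
        with pytest.warns(UserWarning):
            labels = mlcmm.hard_assign(np.array([[0.5, 0.5]]))
        assert labels.tolist() == [0]


class TestMetrics:
    def test_free_parameter_counts(self):
        assert mlcmm.n_free_params(MLCMMSpec(n_classes=4)) == 25
        assert mlcmm.n_free_params(MLCMMSpec(n_classes=3)) == 21
        assert mlcmm.n_free_params(MLCMMSpec(n_classes=1)) == 13

    def test_bic_increases_by_logN_per_parameter(self):
        post = np.full((10, 3), 1 / 3)
        m3 = mlcmm.metrics_from(-100.0, post, MLCMMSpec(n_classes=3), 10)
        m4 = mlcmm.metrics_from(-100.0, post[:, :1].repeat(4, 1) / 4,
                                MLCMMSpec(n_classes=4), 10)
        dp = mlcmm.n_free_params(MLCMMSpec(n_classes=4)) - \
            mlcmm.n_free_params(MLCMMSpec(n_classes=3))
        assert m4["bic"] - m3["bic"] == pytest.approx(dp * np.log(10))

    def test_entropy_range_and_invariance(self):
        crisp = np.eye(4)[np.array([0, 1, 2, 3, 0])]
        assert mlcmm.relative_entropy(crisp) == pytest.approx(1.0)
        uniform = np.full((6, 4), 0.25)
        assert mlcmm.relative_entropy(uniform) == pytest.approx(0.0)
        rng = np.random.default_rng(2)
        post = rng.dirichlet(np.ones(4), size=9)
        assert mlcmm.relative_entropy(post) == pytest.approx(
            mlcmm.relative_entropy(post[:, [3, 1, 0, 2]]))
        assert mlcmm.relative_entropy(np.ones((5, 1))) == 1.0


class TestFit:
    def test_single_class_matches_independent_maximiser(self):
        cfg = synthetic.scenario("small_test", n_subjects=70)
        cohort, _, _ = synthetic.generate_cohort(cfg, seed=21)
        filtered, _ = data_prep.filter_eligible(cohort, require_apoe=True)
        data = MLCMMData.from_cohort(filtered)
        spec = MLCMMSpec(n_classes=1)
        ours = mlcmm.fit(data, spec, n_starts=2, seed=4)
        oracle_ll, oracle_x = maximise_single_class(data)
        assert ours.loglik == pytest.approx(oracle_ll, abs=1e-4)
        # cross-check our reported likelihood with the dense-covariance form
        p = data.X.shape[1]
        theta = np.concatenate([
            ours.params.beta, ours.params.gamma_slope, ours.params.eta1,
            np.log(ours.params.eta2), np.log(ours.params.sigma)])
        assert single_class_loglik_dense(theta, data) == pytest.approx(
            ours.loglik, abs=1e-8)

    def test_seed_determinism(self, crisp_fit_bundle):
        data, spec = crisp_fit_bundle["data"], crisp_fit_bundle["spec"]
        f1 = mlcmm.fit(data, spec, n_starts=2, seed=11)
        f2 = mlcmm.fit(data, spec, n_starts=2, seed=11)
        assert f1.loglik == f2.loglik
        assert np.array_equal(f1.labels, f2.labels)
        assert f1.params.gamma_int == pytest.approx(f2.params.gamma_int)

    def test_crisp_class_recovery(self, crisp_fit_bundle):
        fit = crisp_fit_bundle["fit"]
        truth = crisp_fit_bundle["truth"]
        id_to_class = dict(zip(truth.table.subject_id, truth.table.true_class))
        tc = np.array([id_to_class[s] for s in fit.subject_ids])
        assert adjusted_rand(tc, fit.labels) >= 0.95
        assert fit.converged
        assert fit.posterior.sum(axis=1) == pytest.approx(
            np.ones(len(tc)), abs=1e-10)


class TestPrediction:
    def test_trajectory_round_trip_and_band(self, crisp_fit_bundle):
        fit, data = crisp_fit_bundle["fit"], crisp_fit_bundle["data"]
        times = np.linspace(0, 3, 7)
        cov = mlcmm.observed_information(fit, data)
        traj = mlcmm.predict_trajectory(fit, data, g=1, times=times, cov=cov)
        assert np.all(traj.ci_lower <= traj.latent_mean + 1e-12)
        assert np.all(traj.latent_mean <= traj.ci_upper + 1e-12)
        # outcome-scale curve inverts back to the latent line
        back = data_prep.transform_cdrsb(traj.outcome_curves["cdrsb"])
        lat = (back - fit.params.eta1[0]) / fit.params.eta2[0]
        clipped = np.abs(fit.params.eta1[0] + fit.params.eta2[0]
                         * traj.latent_mean) < 5.19
        assert np.allclose(lat[clipped], traj.latent_mean[clipped], atol=1e-10)

    def test_predict_newdata_matches_training_posterior(self, crisp_fit_bundle):
        fit, data = crisp_fit_bundle["fit"], crisp_fit_bundle["data"]
        sub = data.subset(np.arange(5))
        ids, labels, post = mlcmm.predict_class_newdata(fit, sub)
        assert np.array_equal(ids, sub.subject_ids)
        assert np.allclose(post, fit.posterior[:5], atol=1e-12)

    def test_single_visit_subject_gets_valid_posterior(self, crisp_fit_bundle):
        fit, data = crisp_fit_bundle["fit"], crisp_fit_bundle["data"]
        one = data.subset(np.array([0]))
        keep_first = np.zeros_like(one.mask)
        keep_first[0, 0] = True
        single = MLCMMData(one.subject_ids, one.X, one.y, one.t, one.k,
                           one.mask & keep_first)
        _, labels, post = mlcmm.predict_class_newdata(fit, single)
        assert post.shape == (1, 2)
        assert post.sum() == pytest.approx(1.0)
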