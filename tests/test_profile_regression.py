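"""Dirichlet-process profile regression: sampler correctness and recovery."""

import numpy as np
import pytest
from scipy import stats

from trajclust import profile_regression as pr
from trajclust import synthetic


def _blob_dataset(n=60, centres=(-5.0, 5.0), sd=0.1, seed=0):
    """Two far-separated Gaussian blobs in two continuous dimensions."""
    rng = np.random.default_rng(seed)
    half = n // 2
    labels = np.repeat([0, 1], half)
    x = np.column_stack([
        rng.normal(np.take(centres, labels), sd),
        rng.normal(np.take(centres, labels), sd),
    ])
    data = pr.ProfileDataset(
        subject_ids=np.arange(n), y=labels.copy(), n_classes=2,
        w_bin=np.tile(labels[:, None], (1, 2)).astype(float),
        w_cont=x, bin_names=("b1", "b2"), cont_names=("c1", "c2"),
    )
    return data, labels


class TestInitState:
    def test_deterministic_given_seed(self):
        data, _ = _blob_dataset()
        priors = pr.DPMMPriors(truncation=20)
        s1 = pr.init_state(data, priors, 5)
        s2 = pr.init_state(data, priors, 5)
        assert np.array_equal(s1.alloc, s2.alloc)
        assert np.allclose(s1.theta_bin, s2.theta_bin)
        assert np.allclose(s1.sigma, s2.sigma)

    def test_single_component_truncation(self):
        data, _ = _blob_dataset()
        s = pr.init_state(data, pr.DPMMPriors(truncation=1), 0)
        assert np.all(s.alloc == 0)

    def test_stick_breaking_first_weight(self):
        data, _ = _blob_dataset()
        s = pr.init_state(data, pr.DPMMPriors(truncation=15), 3)
        assert np.exp(s.log_w[0]) == pytest.approx(s.V[0])
        assert np.exp(s.log_w).sum() == pytest.approx(1.0, abs=1e-9)


class TestGibbsSweep:
    def test_single_component_bernoulli_conjugacy(self):
        """With one component forced, the Bernoulli parameter draws must
        follow the Beta conjugate closed form for data (1, 1, 1, 0)."""
        w = np.array([[1.0], [1.0], [1.0], [0.0]])
        data = pr.ProfileDataset(np.arange(4), None, 1, w,
                                 np.zeros((4, 1)), ("b",), ("c",))
        priors = pr.DPMMPriors(truncation=1)
        rng = np.random.default_rng(8)
        state = pr.init_state(data, priors, rng, init_clusters=1)
        draws = []
        for _ in range(2000):
            pr.gibbs_sweep(state, data, priors, rng)
            draws.append(state.theta_bin[0, 0])
        ks = stats.kstest(draws, stats.beta(4.0, 2.0).cdf)
        assert ks.pvalue > 0.01

    def test_separated_blobs_are_separated(self):
        data, labels = _blob_dataset()
        priors = pr.DPMMPriors(truncation=20)
        rng = np.random.default_rng(1)
        state = pr.init_state(data, priors, rng)
        for _ in range(200):
            pr.gibbs_sweep(state, data, priors, rng)
        first = state.alloc[labels == 0]
        second = state.alloc[labels == 1]
        assert len(np.intersect1d(first, second)) == 0

    def test_occupied_cluster_count_grows_with_alpha(self):
        """Prior simulation: E[# occupied components] rises with alpha."""
        rng = np.random.default_rng(4)
        means = []
        for alpha in (0.5, 2.0, 10.0):
            counts = []
            for _ in range(200):
                V = rng.beta(1.0, alpha, size=50)
                V[-1] = 1.0
                w = np.exp(pr._sticks_to_logw(V))
                draws = rng.choice(50, size=200, p=w / w.sum())
                counts.append(len(np.unique(draws)))
            means.append(np.mean(counts))
        assert means[0] < means[1] < means[2]


class TestRunChain:
    def test_kept_iteration_arithmetic_and_determinism(self):
        data, _ = _blob_dataset(n=30)
        priors = pr.DPMMPriors(truncation=10)
        opts = pr.MCMCOptions(n_iter=100, burn_in=50, thin=5, seed=3)
        out = pr.run_chain(data, priors, opts)
        assert out.n_kept == 10
        out2 = pr.run_chain(data, priors, opts)
        assert np.array_equal(out.alloc, out2.alloc)
        assert np.allclose(out.alpha, out2.alpha)

    def test_burnin_must_divide(self):
        with pytest.raises(ValueError):
            pr.MCMCOptions(n_iter=100, burn_in=50, thin=7)

    def test_posterior_cluster_count_on_three_clusters(self):
        cfg = synthetic.scenario("crisp_clusters", n_subjects=120)
        _, profiles, truth = synthetic.generate_cohort(cfg, seed=2)
        out = pr.run_chain(profiles, pr.DPMMPriors(),
                           pr.MCMCOptions(n_iter=1500, burn_in=500, thin=10,
                                          seed=9))
        occupied = np.array([len(np.unique(a)) for a in out.alloc])
        mode = np.bincount(occupied).argmax()
        assert 2 <= mode <= 4

    def test_kept_iteration_log_density_finite(self):
        data, _ = _blob_dataset(n=30)
        out = pr.run_chain(data, pr.DPMMPriors(truncation=10),
                           pr.MCMCOptions(n_iter=200, burn_in=100, thin=10,
                                          seed=5))
        ll = pr.chain_data_loglik(out, data)
        assert np.isfinite(ll).all()


class TestMissingData:
    def test_missing_covariates_are_imputed_and_chain_runs(self):
        data, labels = _blob_dataset(n=40, seed=6)
        w_bin = data.w_bin.copy(); w_bin[::7, 0] = np.nan
        w_cont = data.w_cont.copy(); w_cont[::5, 1] = np.nan
        w_cont[3] = np.nan
        miss = pr.ProfileDataset(data.subject_ids, data.y, 2, w_bin, w_cont,
                                 data.bin_names, data.cont_names)
        out = pr.run_chain(miss, pr.DPMMPriors(truncation=15),
                           pr.MCMCOptions(n_iter=300, burn_in=100, thin=10,
                                          seed=7))
        assert np.isfinite(pr.chain_data_loglik(out, miss)).all()
        # the fully missing subject still lands with its blob most of the time
        psm_col = (out.alloc == out.alloc[:, [3]]).mean(axis=0)
        assert psm_col[labels == labels[3]].mean() > \
            psm_col[labels != labels[3]].mean()


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self):
        data, labels = _blob_dataset(n=60)
        chain = pr.run_chain(data, pr.DPMMPriors(truncation=20),
                             pr.MCMCOptions(n_iter=600, burn_in=200, thin=5,
                                            seed=12))
        return data, labels, chain

    def test_centroid_profile_joins_its_cluster(self, trained):
        data, labels, chain = trained
        new = pr.ProfileDataset(
            np.array([0, 1]), None, 2,
            np.array([[0.0, 0.0], [1.0, 1.0]]),
            np.array([[-5.0, -5.0], [5.0, 5.0]]),
            data.bin_names, data.cont_names)
        alloc = pr.predict_allocation(chain, new, seed=0)
        d_new, d_cross = pr.predicted_dissimilarity(chain, alloc)
        # each new subject co-clusters with its own blob's training members
        for j, blob in enumerate((0, 1)):
            own = d_cross[j, labels == blob].mean()
            other = d_cross[j, labels != blob].mean()
            assert own < 0.1 and other > 0.9
        assert d_new[0, 1] > 0.9
        assert d_new[0, 0] == 0.0

    def test_identical_profiles_identical_distributions(self, trained):
        data, _, chain = trained
        new = pr.ProfileDataset(
            np.array([0, 1]), None, 2,
            np.array([[1.0, 1.0], [1.0, 1.0]]),
            np.array([[5.0, 5.0], [5.0, 5.0]]),
            data.bin_names, data.cont_names)
        alloc = pr.predict_allocation(chain, new, seed=1)
        f0 = np.bincount(alloc[:, 0], minlength=20) / alloc.shape[0]
        f1 = np.bincount(alloc[:, 1], minlength=20) / alloc.shape[0]
        assert np.abs(f0 - f1).max() < 0.12

    def test_all_missing_profile_rejected(self, trained):
        data, _, chain = trained
        new = pr.ProfileDataset(
            np.array([0]), None, 2,
            np.full((1, 2), np.nan), np.full((1, 2), np.nan),
            data.bin_names, data.cont_names)
        with pytest.raises(ValueError):
            pr.predict_allocation(chain, new)


class TestPriors:
    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            pr.DPMMPriors(kappa0=-1.0).resolved(4)
        with pytest.raises(ValueError):
            pr.DPMMPriors(nu0=3.0).resolved(4)

    def test_invwishart_matches_scipy_moments(self):
        """Bartlett-sampled inverse-Wishart agrees with scipy's sampler in
        mean (nu - d - 1 scaling) on a 3-d scale matrix."""
        rng = np.random.default_rng(0)
        psi = np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.2], [0.0, 0.2, 0.5]])
        nu = 12.0
        ours = pr._sample_invwishart(rng, nu, psi, 4000).mean(axis=0)
        expected = psi / (nu - 3 - 1)
        assert np.allclose(ours, expected, atol=0.03)
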