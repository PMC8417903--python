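"""PSM construction, PAM representative clustering and agreement statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import (all_partitions, ari_brute, kappa_brute,
                     pam_optimum_brute, silhouette_brute)
from sklearn.metrics import silhouette_score

from trajclust import cluster_summary as cs
from trajclust import profile_regression as pr


def _block_psm(sizes, within=1.0, between=0.0, seed=None):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    S = np.where(labels[:, None] == labels[None, :], within, between)
    if seed is not None:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(-0.03, 0.03, S.shape)
        noise = 0.5 * (noise + noise.T)
        S = np.clip(S + noise, 0, 1)
    np.fill_diagonal(S, 1.0)
    return cs.SimilarityMatrix(S, np.arange(len(labels))), labels


class TestComputePSM:
    def test_proportions(self):
        alloc = np.array([[0, 1, 1], [0, 1, 2], [0, 0, 2], [1, 0, 0]])
        psm = cs.compute_psm(alloc)
        assert psm.S[0, 1] == pytest.approx(0.25)   # co-clustered 1 of 4
        assert psm.S[0, 0] == 1.0
        psm.validate()

    def test_always_and_never_coclustered(self):
        alloc = np.array([[0, 0, 1], [2, 2, 0]])
        psm = cs.compute_psm(alloc)
        assert psm.S[0, 1] == 1.0 and psm.S[0, 2] == 0.0

    def test_symmetry_diagonal_range_on_random_allocations(self):
        rng = np.random.default_rng(0)
        psm = cs.compute_psm(rng.integers(0, 5, size=(30, 20)))
        psm.validate()


class TestPAM:
    def test_recovers_blocks(self):
        for n_blocks in (2, 3, 4, 5, 6):
            psm, labels = _block_psm([5] * n_blocks)
            got, _ = cs.pam(psm.dissimilarity, n_blocks)
            assert cs.adjusted_rand(got, labels) == 1.0

    def test_objective_reaches_brute_force_optimum(self):
        rng = np.random.default_rng(3)
        for trial in range(15):
            n = rng.integers(4, 7)
            x = rng.normal(0, 1, (n, 2))
            D = np.linalg.norm(x[:, None] - x[None, :], axis=2)
            for k in (2, 3):
                labels, medoids = cs.pam(D, k)
                ours = D[:, medoids].min(axis=1).sum()
                assert ours == pytest.approx(pam_optimum_brute(D, k), abs=1e-9)


class TestRepresentativeClustering:
    def test_silhouette_selects_true_block_count(self):
        for n_blocks in (2, 3, 4):
            psm, labels = _block_psm([8, 6, 7, 5][:n_blocks], within=0.95,
                                     between=0.05, seed=n_blocks)
            rep = cs.representative_clustering(psm, range(2, 7))
            assert rep.chosen_k == n_blocks
            assert cs.adjusted_rand(rep.labels, labels) == 1.0

    def test_degenerate_all_ones_psm(self):
        psm = cs.SimilarityMatrix(np.ones((6, 6)), np.arange(6))
        with pytest.warns(UserWarning):
            rep = cs.representative_clustering(psm)
        assert rep.chosen_k == 1
        assert len(np.unique(rep.labels)) == 1

    def test_silhouette_matches_brute_force(self):
        psm, _ = _block_psm([5, 4, 4], within=0.9, between=0.1, seed=1)
        D = psm.dissimilarity.copy()
        np.fill_diagonal(D, 0)
        labels, _ = cs.pam(D, 3)
        assert silhouette_score(D, labels, metric="precomputed") == \
            pytest.approx(silhouette_brute(D, labels), abs=1e-12)


class TestConsensus:
    def test_mean_and_order_check(self):
        a, _ = _block_psm([4, 4])
        ones = cs.SimilarityMatrix(np.ones((8, 8)), np.arange(8))
        zeros_off = np.zeros((8, 8)); np.fill_diagonal(zeros_off, 1.0)
        zeros = cs.SimilarityMatrix(zeros_off, np.arange(8))
        got = cs.consensus([ones, zeros])
        assert got.S[0, 1] == pytest.approx(0.5)
        assert np.allclose(cs.consensus([a, a]).S, a.S)
        # permutation of chain order is irrelevant
        assert np.allclose(cs.consensus([ones, zeros]).S,
                           cs.consensus([zeros, ones]).S)
        bad = cs.SimilarityMatrix(np.eye(5), np.arange(5))
        with pytest.raises(ValueError):
            cs.consensus([ones, bad])


class TestClusterParamPosteriors:
    def _chain(self, alloc, theta_bin, mu=None):
        R, N = alloc.shape
        H = theta_bin.shape[1]
        return pr.ChainOutput(
            alloc=alloc.astype(np.int16),
            log_w=np.full((R, H), -np.log(H)),
            theta_out=None, theta_bin=theta_bin,
            mu=np.zeros((R, H, 1)) if mu is None else mu,
            sigma=np.tile(np.eye(1), (R, H, 1, 1)),
            alpha=np.ones(R), subject_ids=np.arange(N),
            options=pr.MCMCOptions(n_iter=R, burn_in=0, thin=1, seed=0),
        )

    def test_single_component_equals_parameter_trace(self):
        R, N = 50, 6
        rng = np.random.default_rng(0)
        trace = rng.beta(2, 2, R)
        chain = self._chain(np.zeros((R, N)), trace[:, None, None] *
                            np.ones((R, 1, 1)))
        rep = cs.RepresentativeClustering(
            labels=np.zeros(N, dtype=int), medoids=np.array([0]),
            silhouette_by_k={}, chosen_k=1, subject_ids=np.arange(N))
        out = cs.cluster_param_posteriors([chain], rep)
        row = out[out.parameter == "bern[0]"].iloc[0]
        assert row["mean"] == pytest.approx(trace.mean())
        assert row["ci_lower"] == pytest.approx(np.percentile(trace, 5))

    def test_two_subject_average(self):
        # subjects allocated to components with parameters 0.2 and 0.4
        alloc = np.array([[0, 1]])
        theta = np.array([[[0.2], [0.4]]])
        chain = self._chain(alloc, theta)
        rep = cs.RepresentativeClustering(
            labels=np.zeros(2, dtype=int), medoids=np.array([0]),
            silhouette_by_k={}, chosen_k=1, subject_ids=np.arange(2))
        out = cs.cluster_param_posteriors([chain], rep)
        assert out[out.parameter == "bern[0]"]["mean"].item() == \
            pytest.approx(0.3)

    def test_empty_cluster_rejected(self):
        chain = self._chain(np.zeros((3, 4)), np.ones((3, 1, 1)) * 0.5)
        rep = cs.RepresentativeClustering(
            labels=np.array([0, 0, 0, 2]), medoids=np.array([0, 3]),
            silhouette_by_k={}, chosen_k=2, subject_ids=np.arange(4))
        rep.labels = np.array([0, 0, 0, 0])
        rep2 = cs.RepresentativeClustering(
            labels=np.array([1, 1, 1, 1]), medoids=np.array([0]),
            silhouette_by_k={}, chosen_k=1, subject_ids=np.arange(4))
        out = cs.cluster_param_posteriors([chain], rep2)
        assert (out["cluster"] == 1).all()


class TestAgreementStatistics:
    def test_ari_reference_values(self):
        assert cs.adjusted_rand([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert cs.adjusted_rand([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0
        assert cs.adjusted_rand([1, 1, 2, 2], [1, 2, 1, 2]) == \
            pytest.approx(-0.5)

    def test_kappa_reference_values(self):
        a = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        b = [0] * 40 + [0] * 10 + [1] * 10 + [1] * 40
        assert cs.cohens_kappa(a, b, match=False) == pytest.approx(0.6)
        assert cs.cohens_kappa([0, 1, 0], [0, 1, 0]) == 1.0

    def test_kappa_hungarian_matching_handles_relabelling(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([2, 2, 0, 0, 1, 1])
        assert cs.cohens_kappa(a, b) == 1.0

    def test_kappa_degenerate_flagged(self):
        with pytest.warns(UserWarning):
            out = cs.cohens_kappa([1, 1], [1, 1], match=False)
        assert np.isnan(out)

    def test_brute_force_on_all_small_partitions(self):
        """ARI and kappa agree with their defining formulas on every pair
        of partitions of 5 items."""
        parts = [np.array(p) for p in all_partitions(5)]
        for a, b in itertools.islice(itertools.product(parts, parts), 0, None, 7):
            got = cs.adjusted_rand(a, b)
            want = ari_brute(a, b)
            assert got == pytest.approx(want, abs=1e-12)
            got_k = cs.cohens_kappa(a, b, match=False)
            want_k = kappa_brute(a, b)
            if np.isnan(want_k):
                assert np.isnan(got_k) or got_k == pytest.approx(0.0)
            else:
                assert got_k == pytest.approx(want_k, abs=1e-12)

    def test_lower_triangle_correlation(self):
        psm, _ = _block_psm([4, 4], within=0.9, between=0.1, seed=2)
        assert cs.lower_triangle_correlation(psm, psm) == pytest.approx(1.0)
        flipped = 1 - psm.S
        np.fill_diagonal(flipped, 1.0)
        assert cs.lower_triangle_correlation(
            psm.S, flipped) == pytest.approx(-1.0)
        perm = np.random.default_rng(0).permutation(8)
        assert cs.lower_triangle_correlation(
            psm.S[np.ix_(perm, perm)], flipped[np.ix_(perm, perm)]) == \
            pytest.approx(-1.0)
        with pytest.warns(UserWarning):
            assert np.isnan(cs.lower_triangle_correlation(
                np.ones((4, 4)), np.ones((4, 4))))


class TestChainAgreement:
    def test_duplicate_chains_agree_perfectly(self):
        rng = np.random.default_rng(1)
        alloc = np.repeat(np.array([[0] * 5 + [1] * 5]), 40, axis=0)
        alloc = alloc + rng.integers(0, 1, alloc.shape)
        opts = pr.MCMCOptions(n_iter=40, burn_in=0, thin=1, seed=0)
        mk = lambda: pr.ChainOutput(
            alloc.astype(np.int16), np.zeros((40, 2)), None,
            np.zeros((40, 2, 1)), np.zeros((40, 2, 1)),
            np.tile(np.eye(1), (40, 2, 1, 1)), np.ones(40),
            np.arange(10), opts)
        report = cs.chain_agreement([mk(), mk(), mk()], range(2, 4))
        assert report["mean_pearson"] == pytest.approx(1.0)
        assert report["mean_ari"] == pytest.approx(1.0)
        assert len(report["pairs"]) == 3
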