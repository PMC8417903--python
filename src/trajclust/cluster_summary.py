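"""Post-processing of profile-regression chains into representative clusterings.

The posterior similarity matrix (PSM) S records, for each subject pair, the
proportion of kept MCMC iterations in which the pair shared a mixture
component.  Partitioning around medoids (PAM) applied to the dissimilarity
1 - S gives a representative hard clustering, with the cluster count chosen
by maximising the average silhouette width.  Multi-chain output is
aggregated by element-wise averaging of the chain PSMs (consensus
clustering).  Cluster-averaged component-parameter posteriors quantify the
uncertainty of each representative cluster, and agreement statistics
(adjusted Rand index, Cohen's kappa after Hungarian label matching, Pearson
correlation of lower-triangular dissimilarities) compare partitions and
matrices across chains and analyses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (adjusted_rand_score, cohen_kappa_score,
                             silhouette_score)

from .profile_regression import ChainOutput

__all__ = [
    "SimilarityMatrix",
    "RepresentativeClustering",
    "compute_psm",
    "pooled_psm",
    "pam",
    "representative_clustering",
    "consensus",
    "cluster_param_posteriors",
    "adjusted_rand",
    "match_labels",
    "cohens_kappa",
    "lower_triangle_correlation",
    "chain_agreement",
]


@dataclass
class SimilarityMatrix:
    """N x N posterior co-clustering proportions with the subject order."""

    S: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        self.S = S

    def validate(self) -> None:
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValueError("PSM must be symmetric")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValueError("PSM diagonal must be 1")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValueError("PSM entries must lie in [0, 1]")

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.S

    def restrict(self, idx: np.ndarray) -> "SimilarityMatrix":
        return SimilarityMatrix(self.S[np.ix_(idx, idx)], self.subject_ids[idx])


@dataclass
class RepresentativeClustering:
    """PAM partition of 1 - S with silhouette-selected cluster count."""

    labels: np.ndarray
    medoids: np.ndarray
    silhouette_by_k: dict
    chosen_k: int
    subject_ids: np.ndarray


def compute_psm(alloc: np.ndarray, subject_ids: np.ndarray | None = None
                ) -> SimilarityMatrix:
    """PSM from an (R, N) kept-iteration allocation matrix."""
    alloc = np.asarray(alloc)
    if alloc.ndim != 2 or alloc.shape[0] < 1:
        raise ValueError("need at least one kept iteration of allocations")
    R, N = alloc.shape
    co = np.zeros((N, N), dtype=np.int32)
    for r in range(R):
        a = alloc[r]
        co += (a[:, None] == a[None, :])
    S = co / R
    ids = np.arange(N) if subject_ids is None else np.asarray(subject_ids)
    return SimilarityMatrix(S, ids)


def pooled_psm(chains: list[ChainOutput]) -> SimilarityMatrix:
    """PSM over the pooled kept iterations of several chains (equivalent to
    the weighted consensus of per-chain PSMs for equal kept counts)."""
    alloc = np.concatenate([c.alloc for c in chains], axis=0)
    return compute_psm(alloc, chains[0].subject_ids)


# ---------------------------------------------------------------------------
# PAM (k-medoids): deterministic greedy BUILD + steepest-descent SWAP
# ---------------------------------------------------------------------------

def pam(D: np.ndarray, k: int, max_swaps: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a dissimilarity matrix.

    Deterministic: the BUILD phase seeds medoids greedily (ties toward the
    lower index) and the SWAP phase applies the single best
    cost-reducing (medoid, candidate) exchange until none remains.
    Returns (labels, medoid indices).
    """
    D = np.asarray(D, dtype=float)
    N = D.shape[0]
    if not 1 <= k <= N:
        raise ValueError("k must lie in [1, N]")

    # tiny instances: the medoid set space is small enough to enumerate,
    # which sidesteps the (rare) local optima of build+swap
    from math import comb
    if comb(N, k) <= 3000:
        best_cost, best_medoids = np.inf, None
        for cand in itertools.combinations(range(N), k):
            cost = D[:, cand].min(axis=1).sum()
            if cost < best_cost - 1e-15:
                best_cost, best_medoids = cost, np.array(cand)
        labels = np.argmin(D[:, best_medoids], axis=1)
        return labels, best_medoids

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        # gain of adding candidate j: sum of reductions over points
        gains = np.maximum(cur[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    medoids = np.array(sorted(medoids))
    for _ in range(max_swaps):
        dm = D[:, medoids]                     # (N, k)
        order = np.argsort(dm, axis=1)
        nearest = order[:, 0]
        d1 = dm[np.arange(N), nearest]
        d2 = dm[np.arange(N), order[:, 1]] if k > 1 else np.full(N, np.inf)

        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            # removing medoid mi: points whose nearest is mi fall back to d2
            fallback = np.where(nearest == mi, d2, d1)
            # cost change for every candidate j at once: (N_cand, N_points)
            delta = np.minimum(D, fallback[None, :]).sum(axis=1) - d1.sum()
            delta[medoids] = np.inf
            j = int(np.argmin(delta))
            if delta[j] < best_delta:
                best_delta, best_swap = float(delta[j]), (mi, j)
        if best_swap is None:
            break
        mi, j = best_swap
        medoids[mi] = j
        medoids = np.array(sorted(medoids))
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids


def representative_clustering(psm: SimilarityMatrix,
                              k_range=range(2, 16)) -> RepresentativeClustering:
    """PAM on 1 - S over ``k_range``; the k maximising the average
    silhouette width wins (ties toward smaller k).  A degenerate PSM whose
    off-diagonal entries are all 1 yields a single cluster with a warning."""
    psm.validate()
    D = psm.dissimilarity.copy()
    np.fill_diagonal(D, 0.0)
    N = D.shape[0]
    off = D[~np.eye(N, dtype=bool)]
    if off.size == 0 or np.allclose(off, 0.0):
        warnings.warn("degenerate PSM (all pairs always co-clustered): "
                      "returning a single cluster")
        return RepresentativeClustering(
            labels=np.zeros(N, dtype=int), medoids=np.array([0]),
            silhouette_by_k={}, chosen_k=1, subject_ids=psm.subject_ids)

    best_k, best_sil, best = None, -np.inf, None
    sil_by_k = {}
    for k in k_range:
        if not 2 <= k <= N - 1:
            continue
        labels, medoids = pam(D, k)
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(D, labels, metric="precomputed"))
        sil_by_k[k] = sil
        if sil > best_sil + 1e-12:
            best_k, best_sil, best = k, sil, (labels, medoids)
    if best is None:
        raise ValueError("no k in k_range produced a valid clustering")
    labels, medoids = best
    return RepresentativeClustering(labels, medoids, sil_by_k, best_k,
                                    psm.subject_ids)


def consensus(psms: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Element-wise mean of chain PSMs (consensus similarity)."""
    first = psms[0]
    for p in psms[1:]:
        if p.S.shape != first.S.shape or not np.array_equal(
                p.subject_ids, first.subject_ids):
            raise ValueError("PSMs must share shape and subject order")
    S = np.mean([p.S for p in psms], axis=0)
    return SimilarityMatrix(S, first.subject_ids)


# ---------------------------------------------------------------------------
# cluster-averaged parameter posteriors
# ---------------------------------------------------------------------------

def cluster_param_posteriors(chains: list[ChainOutput],
                             rep: RepresentativeClustering,
                             ci: float = 0.90) -> pd.DataFrame:
    """Posterior summaries of cluster-averaged component parameters.

    For each kept iteration r and representative cluster h, the parameter of
    each member subject's allocated component is averaged over the cluster;
    the trace of these averages across iterations (pooled over chains) is
    summarised by its mean and central credible interval.  Covers the
    outcome simplex, the Bernoulli probabilities and the Gaussian means.
    """
    lo_q, hi_q = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    rows = []
    for h in np.unique(rep.labels):
        members = np.where(rep.labels == h)[0]
        if members.size == 0:
            raise ValueError(f"representative cluster {h} is empty")
        param_traces: dict[str, list[np.ndarray]] = {}
        for chain in chains:
            comp = chain.alloc[:, members].astype(int)     # (R, n_h)
            R = comp.shape[0]
            rr = np.arange(R)[:, None]
            if chain.theta_out is not None:
                for g in range(chain.theta_out.shape[2]):
                    tr = chain.theta_out[rr, comp, g].mean(axis=1)
                    param_traces.setdefault(f"class_prob[{g}]", []).append(tr)
            for q in range(chain.theta_bin.shape[2]):
                tr = chain.theta_bin[rr, comp, q].mean(axis=1)
                param_traces.setdefault(f"bern[{q}]", []).append(tr)
            for c in range(chain.mu.shape[2]):
                tr = chain.mu[rr, comp, c].mean(axis=1)
                param_traces.setdefault(f"gauss_mean[{c}]", []).append(tr)
        for name, traces in param_traces.items():
            trace = np.concatenate(traces)
            rows.append({
                "cluster": int(h), "parameter": name, "n_subjects": len(members),
                "mean": float(trace.mean()),
                "ci_lower": float(np.percentile(trace, lo_q)),
                "ci_upper": float(np.percentile(trace, hi_q)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def adjusted_rand(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def match_labels(labels_ref, labels_other) -> np.ndarray:
    """Relabel ``labels_other`` by Hungarian assignment maximising the
    confusion-table trace against ``labels_ref``."""
    la = np.asarray(labels_ref)
    lb = np.asarray(labels_other)
    cats_a = np.unique(np.concatenate([la, lb]))
    k = len(cats_a)
    index = {c: i for i, c in enumerate(cats_a)}
    conf = np.zeros((k, k))
    for x, y in zip(la, lb):
        conf[index[x], index[y]] += 1
    row, col = linear_sum_assignment(-conf)
    mapping = {cats_a[c]: cats_a[r] for r, c in zip(row, col)}
    return np.array([mapping[v] for v in lb])


def cohens_kappa(labels_a, labels_b, match: bool = True) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e); cluster labels are first
    aligned by Hungarian matching unless ``match=False``.  Returns NaN with
    a warning when chance agreement is 1 (both labellings constant)."""
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    if la.shape != lb.shape:
        raise ValueError("partitions must have equal length")
    if match:
        lb = match_labels(la, lb)
    if len(np.unique(la)) == 1 and len(np.unique(lb)) == 1:
        warnings.warn("kappa undefined: chance agreement is 1")
        return float("nan")
    return float(cohen_kappa_score(la, lb))


def lower_triangle_correlation(S_a, S_b) -> float:
    """Pearson correlation of strictly-lower-triangle entries of two
    similarity or dissimilarity matrices of identical shape/order."""
    A = S_a.S if isinstance(S_a, SimilarityMatrix) else np.asarray(S_a, float)
    B = S_b.S if isinstance(S_b, SimilarityMatrix) else np.asarray(S_b, float)
    if A.shape != B.shape:
        raise ValueError("matrices must share shape")
    il = np.tril_indices(A.shape[0], k=-1)
    a, b = A[il], B[il]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("correlation undefined: a lower triangle is constant")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def chain_agreement(chains: list[ChainOutput],
                    k_range=range(2, 16)) -> dict:
    """Pairwise agreement across chains: lower-triangle Pearson correlation
    of chain PSMs and ARI of chain representative clusterings, with means
    and SDs over the n(n-1)/2 pairs."""
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    psms = [compute_psm(c.alloc, c.subject_ids) for c in chains]
    reps = [representative_clustering(p, k_range) for p in psms]
    pairs = []
    for i, j in itertools.combinations(range(len(chains)), 2):
        pairs.append({
            "chain_a": i, "chain_b": j,
            "pearson_r": lower_triangle_correlation(psms[i], psms[j]),
            "ari": adjusted_rand(reps[i].labels, reps[j].labels),
        })
    df = pd.DataFrame(pairs)
    return {
        "pairs": df,
        "mean_pearson": float(df["pearson_r"].mean()),
        "sd_pearson": float(df["pearson_r"].std(ddof=1)),
        "mean_ari": float(df["ari"].mean()),
        "sd_ari": float(df["ari"].std(ddof=1)),
        "chain_psms": psms,
        "chain_clusterings": reps,
    }
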