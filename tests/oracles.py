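"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package
implementation it checks: numerical quadrature for marginal likelihoods,
dense-covariance Gaussian densities for the single-class model, and
brute-force evaluations of the partition-agreement statistics.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import multivariate_normal


def subject_loglik_quadrature(params, data, i, g, n_nodes=150):
    """Class-conditional subject log-likelihood by Gauss-Hermite quadrature
    over the random intercept (instead of the closed form)."""
    mask = data.mask[i]
    y = data.y[i][mask]
    t = data.t[i][mask]
    k = data.k[i][mask]
    x = data.X[i]
    eta1, eta2 = params.eta1[k], params.eta2[k]
    ytil = (y - eta1) / eta2
    mu = x @ params.beta + params.gamma_int[g] + params.gamma_slope[g] * t
    sd = params.sigma[k]
    omega = params.omega[g]

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    # adaptive rule: centre and scale the nodes at the mode/curvature of the
    # integrand (from completing the square in u), so sharp or displaced
    # posteriors stay inside the node range
    r = ytil - mu
    prec = (1.0 / sd ** 2).sum() + 1.0 / omega
    u_hat = (r / sd ** 2).sum() / prec
    c = np.sqrt(2.0 / prec)
    u = u_hat + c * nodes
    log_g = np.zeros(n_nodes)
    for q in range(n_nodes):
        z = (ytil - mu - u[q]) / sd
        log_g[q] = (-0.5 * (z ** 2).sum()
                    - np.log(sd * np.sqrt(2 * np.pi)).sum()
                    - 0.5 * u[q] ** 2 / omega
                    - 0.5 * np.log(2 * np.pi * omega))
    val = logsumexp(np.log(weights) + nodes ** 2 + log_g) + np.log(c)
    return val - np.log(eta2).sum()


def mixture_loglik_quadrature(params, data, n_nodes=150):
    """Full mixture log-likelihood via the quadrature oracle."""
    G = len(params.gamma_int)
    pi = np.exp(params.xi0 - params.xi0.max())
    pi /= pi.sum()
    total = 0.0
    for i in range(data.n_subjects):
        per_class = [subject_loglik_quadrature(params, data, i, g, n_nodes)
                     for g in range(G)]
        m = max(per_class)
        total += m + np.log(sum(p * np.exp(v - m)
                                for p, v in zip(pi, per_class)))
    return total


def single_class_loglik_dense(theta, data):
    """G = 1 log-likelihood with explicitly built dense covariance matrices
    (omega fixed at 1, intercept fixed at 0, per the reference conventions).

    theta = (beta[p], slope, eta1[2], log eta2[2], log sigma[2]).
    """
    p = data.X.shape[1]
    beta = theta[:p]
    slope = theta[p]
    eta1 = theta[p + 1:p + 3]
    eta2 = np.exp(theta[p + 3:p + 5])
    sigma = np.exp(theta[p + 5:p + 7])
    total = 0.0
    for i in range(data.n_subjects):
        mask = data.mask[i]
        y = data.y[i][mask]
        t = data.t[i][mask]
        k = data.k[i][mask]
        ytil = (y - eta1[k]) / eta2[k]
        mu = data.X[i] @ beta + slope * t
        cov = np.ones((mask.sum(), mask.sum())) + np.diag(sigma[k] ** 2)
        total += multivariate_normal.logpdf(ytil, mean=mu, cov=cov)
        total -= np.log(eta2[k]).sum()
    return total


def maximise_single_class(data, x0=None):
    """Independently coded G = 1 maximiser (quasi-Newton on the dense-
    covariance likelihood with numerical gradients)."""
    p = data.X.shape[1]
    if x0 is None:
        x0 = np.zeros(p + 7)
        for kk in range(2):
            vals = data.y[data.mask & (data.k == kk)]
            x0[p + 1 + kk] = vals.mean()
            x0[p + 3 + kk] = np.log(max(vals.std(), 1e-3))
        x0[p + 5:p + 7] = np.log(0.5)
    best = None
    for start in (x0, x0 + 0.1):
        res = minimize(lambda th: -single_class_loglik_dense(th, data),
                       start, method="BFGS",
                       options={"maxiter": 2000, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, best.x


# ---------------------------------------------------------------------------
# partition statistics by brute force
# ---------------------------------------------------------------------------

def ari_brute(a, b):
    """Adjusted Rand index straight from the pair-counting definition."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, 1)
    n11 = int((same_a[iu] & same_b[iu]).sum())
    n10 = int((same_a[iu] & ~same_b[iu]).sum())
    n01 = int((~same_a[iu] & same_b[iu]).sum())
    n00 = int((~same_a[iu] & ~same_b[iu]).sum())
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total if total else 0.0
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def kappa_brute(a, b):
    """Cohen's kappa from observed and chance agreement."""
    a, b = np.asarray(a), np.asarray(b)
    cats = np.unique(np.concatenate([a, b]))
    po = float((a == b).mean())
    pe = sum(float((a == c).mean()) * float((b == c).mean()) for c in cats)
    if pe == 1.0:
        return np.nan
    return (po - pe) / (1 - pe)


def silhouette_brute(D, labels):
    """Average silhouette width from its per-point definition."""
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    n = len(labels)
    widths = []
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        a = D[i][own].mean() if own.any() else 0.0
        bs = [D[i][labels == c].mean() for c in np.unique(labels)
              if c != labels[i]]
        b = min(bs)
        widths.append(0.0 if own.sum() == 0 else (b - a) / max(a, b))
    return float(np.mean(widths))


def pam_optimum_brute(D, k):
    """Globally optimal k-medoids objective by exhaustive enumeration."""
    D = np.asarray(D, float)
    n = D.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = D[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return best


def all_partitions(n):
    """Every partition of n items as a label vector (restricted growth)."""
    def rec(prefix, m):
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(m + 1):
            yield from rec(prefix + [lab], max(m, lab + 1))
    yield from rec([0], 1)
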