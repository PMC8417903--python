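"""Bayesian profile regression: outcome-guided Dirichlet-process clustering.

A Dirichlet-process mixture links a categorical outcome (the latent
trajectory class from the first modelling stage) to a mixed biomarker
profile: Q binary covariates with independent Bernoulli likelihoods and a
C-dimensional continuous block with a full multivariate-Gaussian likelihood,
all conditionally independent given cluster membership,

    p(y*, w_d, w_c) = sum_h  pi*_h  Cat(y* | theta_h^o)
                      prod_q Bern(w_dq | theta_hq^d)  N_C(w_c | mu_h, Sigma_h).

The stick-breaking prior pi*_1 = V_1, pi*_h = V_h prod_{l<h}(1 - V_l),
V_h ~ Beta(1, alpha), is truncated at H components and sampled by a blocked
Gibbs sampler: allocations, sticks, conjugate component-parameter updates
(Beta, Dirichlet, normal-inverse-Wishart), a conjugate Gamma update for the
concentration alpha, and within-MCMC imputation of missing covariates from
the allocated component.  Held-out subjects are allocated per kept iteration
from their covariate likelihood alone (outcome omitted), which yields
predicted co-clustering (dis)similarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProfileDataset",
    "DPMMPriors",
    "DPMMState",
    "MCMCOptions",
    "ChainOutput",
    "init_state",
    "gibbs_sweep",
    "run_chain",
    "run_chains",
    "predict_allocation",
    "predicted_dissimilarity",
    "chain_data_loglik",
]

BIN_NAMES = ("ad_positive", "mta_flag", "fsd_flag", "fspv_flag", "arwmc_flag")
CONT_NAMES = ("hv", "vv", "hv_rate", "vv_rate")


# ---------------------------------------------------------------------------
# data, priors, state
# ---------------------------------------------------------------------------

@dataclass
class ProfileDataset:
    """Per-subject profile: outcome class, binary and continuous covariates.

    ``y`` may be None for the biomarker-only reference clustering.  Missing
    covariates are NaN; the outcome must be observed for every training
    subject.
    """

    subject_ids: np.ndarray
    y: np.ndarray | None          # (N,) int in 0..G-1, or None
    n_classes: int
    w_bin: np.ndarray             # (N, Q) in {0, 1} with NaN for missing
    w_cont: np.ndarray            # (N, C) standardised, NaN for missing
    bin_names: tuple = BIN_NAMES
    cont_names: tuple = CONT_NAMES

    def __post_init__(self):
        self.w_bin = np.asarray(self.w_bin, dtype=float)
        self.w_cont = np.asarray(self.w_cont, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if np.any((self.y < 0) | (self.y >= self.n_classes)):
                raise ValueError("outcome classes out of range")
            if len(self.y) != len(self.subject_ids):
                raise ValueError("outcome length mismatch")
        obs = self.w_bin[~np.isnan(self.w_bin)]
        if obs.size and not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError("binary covariates must be 0/1 or NaN")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def without_outcome(self) -> "ProfileDataset":
        return ProfileDataset(self.subject_ids, None, self.n_classes,
                              self.w_bin, self.w_cont,
                              self.bin_names, self.cont_names)

    def subset(self, idx: np.ndarray) -> "ProfileDataset":
        return ProfileDataset(
            self.subject_ids[idx],
            None if self.y is None else self.y[idx],
            self.n_classes, self.w_bin[idx], self.w_cont[idx],
            self.bin_names, self.cont_names,
        )


@dataclass
class DPMMPriors:
    """Conjugate hyperpriors.  Defaults: Beta(1,1) on Bernoulli parameters,
    symmetric Dirichlet(1) on the outcome simplex, a weakly informative
    normal-inverse-Wishart (mu0 = 0, kappa0 = 0.01, nu0 = dim + 2,
    Psi0 = I; covariates standardised) and alpha ~ Gamma(2, 1)."""

    a0: float = 1.0
    b0: float = 1.0
    delta: float = 1.0
    mu0: np.ndarray | None = None
    kappa0: float = 0.01
    nu0: float | None = None
    psi0: np.ndarray | None = None
    alpha_shape: float = 2.0
    alpha_rate: float = 1.0
    truncation: int = 50

    def resolved(self, dim: int) -> "DPMMPriors":
        out = DPMMPriors(**{**self.__dict__})
        out.mu0 = np.zeros(dim) if self.mu0 is None else np.asarray(self.mu0, float)
        out.nu0 = float(dim + 2) if self.nu0 is None else float(self.nu0)
        out.psi0 = np.eye(dim) if self.psi0 is None else np.asarray(self.psi0, float)
        if min(self.a0, self.b0, self.delta, self.kappa0,
               self.alpha_shape, self.alpha_rate) <= 0:
            raise ValueError("hyperparameters must be positive")
        if out.nu0 <= dim + 1:
            raise ValueError("nu0 must exceed dim + 1")
        if self.truncation < 1:
            raise ValueError("truncation must be >= 1")
        return out


@dataclass
class DPMMState:
    """Current Gibbs state: allocations, sticks, component parameters,
    concentration and the imputed covariate arrays."""

    alloc: np.ndarray             # (N,)
    V: np.ndarray                 # (H,)
    log_w: np.ndarray             # (H,)
    theta_out: np.ndarray | None  # (H, G)
    theta_bin: np.ndarray         # (H, Q)
    mu: np.ndarray                # (H, C)
    sigma: np.ndarray             # (H, C, C)
    alpha: float
    w_bin_filled: np.ndarray      # (N, Q), NaN only before first imputation
    w_cont_filled: np.ndarray     # (N, C)


@dataclass
class MCMCOptions:
    """Sampler settings.  Desk-scale defaults: 20,000 iterations with 5,000
    burn-in, thinning 10, over 6 chains."""

    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 10
    seed: int | None = None
    init_clusters: int = 10

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if (self.n_iter - self.burn_in) % self.thin:
            raise ValueError("n_iter - burn_in must be divisible by thin")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ChainOutput:
    """Kept draws from one chain: allocations plus everything needed for
    cluster-averaged parameter posteriors and held-out prediction."""

    alloc: np.ndarray        # (R, N) int16
    log_w: np.ndarray        # (R, H)
    theta_out: np.ndarray | None   # (R, H, G)
    theta_bin: np.ndarray    # (R, H, Q)
    mu: np.ndarray           # (R, H, C)
    sigma: np.ndarray        # (R, H, C, C)
    alpha: np.ndarray        # (R,)
    subject_ids: np.ndarray
    options: MCMCOptions
    last_component_hits: int = 0

    @property
    def n_kept(self) -> int:
        return self.alloc.shape[0]


# ---------------------------------------------------------------------------
# random-variate helpers
# ---------------------------------------------------------------------------

def _sample_invwishart(rng, nu: float, psi: np.ndarray, size: int) -> np.ndarray:
    """Batched inverse-Wishart draws via the Bartlett decomposition.

    If W ~ Wishart(nu, psi^{-1}) then W^{-1} ~ IW(nu, psi).
    """
    d = psi.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(psi))
    A = np.zeros((size, d, d))
    for i in range(d):
        A[:, i, i] = np.sqrt(rng.chisquare(nu - i, size=size))
    tri = np.tril_indices(d, k=-1)
    A[:, tri[0], tri[1]] = rng.standard_normal((size, len(tri[0])))
    LA = L[None] @ A
    W = LA @ np.transpose(LA, (0, 2, 1))
    return np.linalg.inv(W)


def _sample_niw(rng, mu0, kappa0, nu, psi, size: int):
    """Batched normal-inverse-Wishart draws (Sigma, then mu | Sigma)."""
    sigma = _sample_invwishart(rng, nu, psi, size)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((size, psi.shape[0]))
    mu = mu0[None] + (chol @ z[:, :, None])[:, :, 0] / np.sqrt(kappa0)
    return mu, sigma


def _dirichlet_rows(rng, alpha_mat: np.ndarray) -> np.ndarray:
    g = rng.gamma(alpha_mat)
    return g / g.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# likelihood pieces (NaN entries contribute nothing: factor skipped)
# ---------------------------------------------------------------------------

def _bin_loglik(w_bin: np.ndarray, theta_bin: np.ndarray) -> np.ndarray:
    """(N, H) Bernoulli log-likelihood, missing entries skipped."""
    th = np.clip(theta_bin, 1e-12, 1 - 1e-12)
    w = np.nan_to_num(w_bin, nan=0.0)
    obs = ~np.isnan(w_bin)
    # log lik = sum_q [ w log th + (1-w) log(1-th) ] over observed q
    t1 = np.log(th)          # (H, Q)
    t0 = np.log1p(-th)
    return (w * obs) @ t1.T + ((1 - w) * obs) @ t0.T


def _gauss_loglik(w_cont: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """(N, H) Gaussian log-likelihood with marginalisation over missing
    entries (grouped by missingness pattern)."""
    N, C = w_cont.shape
    H = mu.shape[0]
    out = np.zeros((N, H))
    obs = ~np.isnan(w_cont)
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    for p_idx, pat in enumerate(patterns):
        rows = np.where(inverse == p_idx)[0]
        d = int(pat.sum())
        if d == 0:
            continue
        cols = np.where(pat)[0]
        x = w_cont[np.ix_(rows, cols)]                      # (n, d)
        mu_p = mu[:, cols]                                  # (H, d)
        sig_p = sigma[np.ix_(np.arange(H), cols, cols)]     # (H, d, d)
        L = np.linalg.cholesky(sig_p)
        diff = x[None, :, :] - mu_p[:, None, :]             # (H, n, d)
        sol = np.linalg.solve(L, np.swapaxes(diff, 1, 2))   # (H, d, n)
        quad = (sol ** 2).sum(axis=1)                       # (H, n)
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
        out[rows, :] = (-0.5 * (d * np.log(2 * np.pi)
                                + logdet[:, None] + quad)).T
    return out


def _allocation_logprobs(state: DPMMState, data: ProfileDataset,
                         include_outcome: bool = True) -> np.ndarray:
    logp = state.log_w[None, :].copy()
    logp = np.broadcast_to(logp, (data.n_subjects, len(state.log_w))).copy()
    if include_outcome and data.y is not None and state.theta_out is not None:
        logp += np.log(np.clip(state.theta_out[:, data.y], 1e-300, None)).T
    logp += _bin_loglik(state.w_bin_filled, state.theta_bin)
    logp += _gauss_loglik(state.w_cont_filled, state.mu, state.sigma)
    return logp


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def init_state(data: ProfileDataset, priors: DPMMPriors,
               seed_or_rng=None, init_clusters: int = 10) -> DPMMState:
    """Initial state: uniform allocations over ``init_clusters`` components,
    parameters drawn from their priors, alpha from its Gamma prior."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    C = data.w_cont.shape[1]
    Q = data.w_bin.shape[1]
    pr = priors.resolved(C)
    H = pr.truncation
    alpha = rng.gamma(pr.alpha_shape, 1.0 / pr.alpha_rate)
    V = rng.beta(1.0, alpha, size=H)
    V[-1] = 1.0
    log_w = _sticks_to_logw(V)
    alloc = rng.integers(0, min(init_clusters, H), size=data.n_subjects)
    theta_out = None
    if data.y is not None:
        theta_out = _dirichlet_rows(rng, np.full((H, data.n_classes), pr.delta))
    theta_bin = rng.beta(pr.a0, pr.b0, size=(H, Q))
    mu, sigma = _sample_niw(rng, pr.mu0, pr.kappa0, pr.nu0, pr.psi0, H)
    return DPMMState(alloc, V, log_w, theta_out, theta_bin, mu, sigma,
                     alpha, data.w_bin.copy(), data.w_cont.copy())


def _sticks_to_logw(V: np.ndarray) -> np.ndarray:
    Vc = np.clip(V, 1e-12, 1.0)
    log1m = np.log1p(-np.clip(V, 0.0, 1 - 1e-12))
    cum = np.concatenate([[0.0], np.cumsum(log1m[:-1])])
    return np.log(Vc) + cum


def gibbs_sweep(state: DPMMState, data: ProfileDataset, priors: DPMMPriors,
                rng: np.random.Generator) -> DPMMState:
    """One full blocked-Gibbs update (in place; state returned).

    Order: allocations | sticks | missing-covariate imputation from the
    allocated component | conjugate component-parameter updates | alpha.
    Imputation precedes the parameter update so conjugate updates always see
    complete data; on the very first sweep the allocation step simply skips
    the factors of still-missing covariates.
    """
    C = data.w_cont.shape[1]
    pr = priors.resolved(C)
    H = pr.truncation
    N = data.n_subjects

    # (1) allocations -- Gumbel-max over components, log space
    logp = _allocation_logprobs(state, data, include_outcome=True)
    gumb = rng.gumbel(size=logp.shape)
    state.alloc = np.argmax(logp + gumb, axis=1)

    # (2) sticks
    n_h = np.bincount(state.alloc, minlength=H).astype(float)
    tail = np.concatenate([np.cumsum(n_h[::-1])[::-1][1:], [0.0]])
    V = rng.beta(1.0 + n_h, state.alpha + tail)
    V[-1] = 1.0
    state.V = V
    state.log_w = _sticks_to_logw(V)

    # (3) impute missing covariates from the allocated component
    _impute_missing(state, data, rng)

    # (4) component parameters from conjugate posteriors
    if data.y is not None:
        counts = np.zeros((H, data.n_classes))
        np.add.at(counts, (state.alloc, data.y), 1.0)
        state.theta_out = _dirichlet_rows(rng, pr.delta + counts)
    Q = data.w_bin.shape[1]
    succ = np.zeros((H, Q)); tot = np.zeros((H, 1))
    np.add.at(succ, state.alloc, state.w_bin_filled)
    np.add.at(tot[:, 0], state.alloc, 1.0)
    state.theta_bin = rng.beta(pr.a0 + succ, pr.b0 + (tot - succ))

    occupied = np.where(n_h > 0)[0]
    empty = np.where(n_h == 0)[0]
    if empty.size:
        mu_e, sig_e = _sample_niw(rng, pr.mu0, pr.kappa0, pr.nu0, pr.psi0,
                                  empty.size)
        state.mu[empty] = mu_e
        state.sigma[empty] = sig_e
    for h in occupied:
        x = state.w_cont_filled[state.alloc == h]
        n = len(x)
        xbar = x.mean(axis=0)
        S = (x - xbar).T @ (x - xbar)
        kappa_n = pr.kappa0 + n
        nu_n = pr.nu0 + n
        mu_n = (pr.kappa0 * pr.mu0 + n * xbar) / kappa_n
        dev = (xbar - pr.mu0)[:, None]
        psi_n = pr.psi0 + S + (pr.kappa0 * n / kappa_n) * (dev @ dev.T)
        mu_h, sig_h = _sample_niw(rng, mu_n, kappa_n, nu_n, psi_n, 1)
        state.mu[h] = mu_h[0]
        state.sigma[h] = sig_h[0]

    # (5) concentration: Escobar-West auxiliary-variable update, with the
    # occupied-component count of the truncated sampler playing the role of
    # the number of clusters
    k_occ = int((n_h > 0).sum())
    eta = rng.beta(state.alpha + 1.0, max(N, 1))
    rate = pr.alpha_rate - np.log(max(eta, 1e-300))
    odds = (pr.alpha_shape + k_occ - 1.0) / (N * rate)
    shape = pr.alpha_shape + k_occ - (0.0 if rng.random() < odds / (1 + odds)
                                      else 1.0)
    state.alpha = rng.gamma(shape, 1.0 / rate)
    return state


def _impute_missing(state: DPMMState, data: ProfileDataset,
                    rng: np.random.Generator) -> None:
    miss_b = np.isnan(data.w_bin)
    if miss_b.any():
        rows, cols = np.where(miss_b)
        p = state.theta_bin[state.alloc[rows], cols]
        state.w_bin_filled[rows, cols] = (rng.random(len(rows)) < p).astype(float)
    miss_c = np.isnan(data.w_cont)
    if not miss_c.any():
        return
    # group by (missingness pattern, allocated component): rows in a group
    # share the conditional-Gaussian matrices and can be drawn in one batch
    rows_any = np.where(miss_c.any(axis=1))[0]
    patterns, inverse = np.unique(miss_c[rows_any], axis=0, return_inverse=True)
    for p_idx, m in enumerate(patterns):
        prows = rows_any[inverse == p_idx]
        o = ~m
        for h in np.unique(state.alloc[prows]):
            rows = prows[state.alloc[prows] == h]
            mu, sig = state.mu[h], state.sigma[h]
            if not o.any():
                L = np.linalg.cholesky(sig)
                z = rng.standard_normal((len(rows), len(mu)))
                state.w_cont_filled[np.ix_(rows, np.where(m)[0])] = \
                    (mu[None, :] + z @ L.T)[:, m]
                continue
            Soo = sig[np.ix_(o, o)]
            Smo = sig[np.ix_(m, o)]
            Smm = sig[np.ix_(m, m)]
            gain = np.linalg.solve(Soo, Smo.T).T          # (n_m, n_o)
            cond_mu = mu[m][None, :] + (data.w_cont[np.ix_(rows, np.where(o)[0])]
                                        - mu[o][None, :]) @ gain.T
            cond_S = Smm - gain @ Smo.T
            cond_S = 0.5 * (cond_S + cond_S.T) + 1e-12 * np.eye(int(m.sum()))
            L = np.linalg.cholesky(cond_S)
            z = rng.standard_normal((len(rows), int(m.sum())))
            state.w_cont_filled[np.ix_(rows, np.where(m)[0])] = cond_mu + z @ L.T


def run_chain(data: ProfileDataset, priors: DPMMPriors,
              options: MCMCOptions) -> ChainOutput:
    """Run one chain; burn-in discarded, allocations and component
    parameters stored every ``thin`` iterations.  Reproducible given the
    seed.  Warns if the truncation's last component is ever occupied."""
    rng = np.random.default_rng(options.seed)
    C = data.w_cont.shape[1]
    pr = priors.resolved(C)
    H = pr.truncation
    state = init_state(data, priors, rng, options.init_clusters)

    R = options.n_kept
    N, Q = data.w_bin.shape
    keep_alloc = np.empty((R, N), dtype=np.int16)
    keep_logw = np.empty((R, H))
    keep_tout = (np.empty((R, H, data.n_classes)) if data.y is not None else None)
    keep_tbin = np.empty((R, H, Q))
    keep_mu = np.empty((R, H, C))
    keep_sig = np.empty((R, H, C, C))
    keep_alpha = np.empty(R)
    last_hits = 0

    r = 0
    for it in range(1, options.n_iter + 1):
        gibbs_sweep(state, data, priors, rng)
        if (state.alloc == H - 1).any():
            last_hits += 1
        if it > options.burn_in and (it - options.burn_in) % options.thin == 0:
            keep_alloc[r] = state.alloc
            keep_logw[r] = state.log_w
            if keep_tout is not None:
                keep_tout[r] = state.theta_out
            keep_tbin[r] = state.theta_bin
            keep_mu[r] = state.mu
            keep_sig[r] = state.sigma
            keep_alpha[r] = state.alpha
            r += 1
    if last_hits:
        warnings.warn(
            f"truncation boundary component occupied in {last_hits} sweeps; "
            "consider raising the truncation level"
        )
    return ChainOutput(keep_alloc, keep_logw, keep_tout, keep_tbin, keep_mu,
                       keep_sig, keep_alpha, data.subject_ids, options,
                       last_hits)


def run_chains(data: ProfileDataset, priors: DPMMPriors, n_chains: int = 6,
               seed: int | None = None, **opt_kwargs) -> list[ChainOutput]:
    """Independent chains with seeds spawned from ``seed``."""
    root = np.random.SeedSequence(seed)
    outs = []
    for child in root.spawn(n_chains):
        chain_seed = int(child.generate_state(1)[0] % (2 ** 31))
        outs.append(run_chain(data, priors,
                              MCMCOptions(seed=chain_seed, **opt_kwargs)))
    return outs


# ---------------------------------------------------------------------------
# held-out prediction
# ---------------------------------------------------------------------------

def predict_allocation(chain: ChainOutput, new_data: ProfileDataset,
                       seed: int | None = None) -> np.ndarray:
    """Per-kept-iteration allocation of new subjects from their covariate
    likelihood alone (the outcome factor is omitted: held-out subjects'
    classes are the quantity being predicted).  Returns an (R, M) matrix."""
    if (np.isnan(new_data.w_bin).all(axis=1)
            & np.isnan(new_data.w_cont).all(axis=1)).any():
        raise ValueError("a new profile has every covariate missing")
    rng = np.random.default_rng(seed)
    R = chain.n_kept
    M = new_data.n_subjects
    out = np.empty((R, M), dtype=np.int16)
    for r in range(R):
        logp = chain.log_w[r][None, :] \
            + _bin_loglik(new_data.w_bin, chain.theta_bin[r]) \
            + _gauss_loglik(new_data.w_cont, chain.mu[r], chain.sigma[r])
        out[r] = np.argmax(logp + rng.gumbel(size=logp.shape), axis=1)
    return out


def predicted_dissimilarity(chain: ChainOutput, new_alloc: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted dissimilarities from held-out allocation samples.

    Returns ``(D_new, D_cross)``: 1 - co-clustering proportion among the
    new subjects (M x M) and between new and training subjects (M x N).
    """
    R, M = new_alloc.shape
    N = chain.alloc.shape[1]
    co_new = np.zeros((M, M))
    co_cross = np.zeros((M, N))
    for r in range(R):
        a = new_alloc[r]
        co_new += (a[:, None] == a[None, :])
        co_cross += (a[:, None] == chain.alloc[r][None, :])
    return 1.0 - co_new / R, 1.0 - co_cross / R


def chain_data_loglik(chain: ChainOutput, data: ProfileDataset) -> np.ndarray:
    """Kept-iteration trace of the allocated-data log density
    sum_i [log pi*_{c_i} + log f(D_i | theta_{c_i})] (finite at every kept
    iteration for a healthy chain)."""
    R = chain.n_kept
    out = np.empty(R)
    idx = np.arange(data.n_subjects)
    for r in range(R):
        st = DPMMState(
            chain.alloc[r].astype(int), None, chain.log_w[r],
            None if chain.theta_out is None else chain.theta_out[r],
            chain.theta_bin[r], chain.mu[r], chain.sigma[r],
            chain.alpha[r], data.w_bin, data.w_cont,
        )
        logp = _allocation_logprobs(st, data, include_outcome=True)
        out[r] = logp[idx, chain.alloc[r]].sum()
    return out
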