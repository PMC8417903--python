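"""Multivariate latent-class linear mixed effects model (MLCMM).

A shared latent process Lambda_i(t) drives K longitudinal outcomes through
outcome-specific linear links.  Conditional on membership of latent class g,

    Ytilde_ijk = Lambda_i(t_ijk) + eps_ijk,
    Lambda_i(t) = x_i' beta + gamma_g0 + gamma_g1 * t + u_ig,

where Ytilde_ijk = (Y_ijk - eta_1k) / eta_2k is the linearly linked outcome
k, eps_ijk ~ N(0, sigma_k^2) are independent measurement errors on the
latent scale, and u_ig ~ N(0, omega_g * B) is a class-specific random
intercept (B = 1 fixed).  Class membership follows a multinomial logistic
model without covariates: P(c_i = g) = softmax(xi_0)_g.

Identifiability conventions (all reference indices configurable):
the fixed intercept of class 0 is 0, the random-intercept variance of the
last class is 1 (omega_last = 1, B = 1), and the membership logit of the
last class is 0.  With K = 2 outcomes and p covariates this gives
3(G-1) + G + p + 3K free parameters (25 for G = 4, p = 6).

Estimation is maximum likelihood: the observed-data mixture log-likelihood
(marginal over the random intercept, in closed form for the
random-intercept-only structure) is maximised by multi-start quasi-Newton
(L-BFGS-B) in an unconstrained parameterisation (log transforms for
eta_2, sigma, omega).  Missing outcomes at a visit are handled under MAR by
restricting each subject's Gaussian to observed entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data_prep import CohortTable, load_mmse_lookup, normalise_mmse, transform_cdrsb

__all__ = [
    "MLCMMSpec",
    "MLCMMParams",
    "MLCMMData",
    "MLCMMFit",
    "DEFAULT_COVARIATES",
    "design_matrix",
    "n_free_params",
    "latent_mean",
    "class_probabilities",
    "subject_class_loglik",
    "log_likelihood",
    "fit",
    "posterior_class_probs",
    "hard_assign",
    "metrics",
    "relative_entropy",
    "relabel_classes",
    "standard_errors",
    "predict_trajectory",
    "predict_class_newdata",
]

DEFAULT_COVARIATES = ("age", "sex_male", "edu2", "edu3", "family_history", "apoe4")

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# specification and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLCMMSpec:
    """Model structure: class count, covariates and reference conventions."""

    n_classes: int
    n_covariates: int = 6
    n_outcomes: int = 2
    ref_intercept_class: int = 0     # gamma intercept fixed at 0
    ref_variance_class: int = -1     # omega fixed at 1 (B = 1)
    ref_membership_class: int = -1   # xi0 fixed at 0

    def __post_init__(self):
        G = self.n_classes
        if G < 1:
            raise ValueError("n_classes must be >= 1")
        for name in ("ref_intercept_class", "ref_variance_class",
                     "ref_membership_class"):
            idx = getattr(self, name)
            if not -G <= idx < G:
                raise ValueError(f"{name}={idx} out of range for G={G}")

    def _ref(self, which: str) -> int:
        return getattr(self, which) % self.n_classes


@dataclass
class MLCMMParams:
    """Natural-scale parameters, including the fixed reference entries."""

    xi0: np.ndarray          # (G,) membership logits, reference entry 0
    beta: np.ndarray         # (p,) class-independent fixed effects
    gamma_int: np.ndarray    # (G,) class intercepts, reference entry 0
    gamma_slope: np.ndarray  # (G,) class time-in-study slopes
    eta1: np.ndarray         # (K,) link locations
    eta2: np.ndarray         # (K,) link scales, > 0
    sigma: np.ndarray        # (K,) measurement-error SDs, > 0
    omega: np.ndarray        # (G,) random-intercept variances, reference 1

    def copy(self) -> "MLCMMParams":
        return MLCMMParams(**{k: np.array(v) for k, v in self.__dict__.items()})


def n_free_params(spec: MLCMMSpec) -> int:
    """Free-parameter count: fixed reference entries are excluded."""
    G, p, K = spec.n_classes, spec.n_covariates, spec.n_outcomes
    return (G - 1) + (G - 1) + G + p + 2 * K + K + (G - 1)


# --- packing of the free parameters into an unconstrained vector -----------

def _free_mask(G: int, ref: int) -> np.ndarray:
    m = np.ones(G, dtype=bool)
    m[ref] = False
    return m


def _pack(params: MLCMMParams, spec: MLCMMSpec) -> np.ndarray:
    G = spec.n_classes
    return np.concatenate([
        params.xi0[_free_mask(G, spec._ref("ref_membership_class"))],
        params.gamma_int[_free_mask(G, spec._ref("ref_intercept_class"))],
        params.gamma_slope,
        params.beta,
        params.eta1,
        np.log(params.eta2),
        np.log(params.sigma),
        np.log(params.omega[_free_mask(G, spec._ref("ref_variance_class"))]),
    ])


def _unpack(vec: np.ndarray, spec: MLCMMSpec) -> MLCMMParams:
    G, p, K = spec.n_classes, spec.n_covariates, spec.n_outcomes
    i = 0

    def take(n):
        nonlocal i
        out = vec[i:i + n]
        i += n
        return np.asarray(out, dtype=float)

    xi0 = np.zeros(G)
    xi0[_free_mask(G, spec._ref("ref_membership_class"))] = take(G - 1)
    gint = np.zeros(G)
    gint[_free_mask(G, spec._ref("ref_intercept_class"))] = take(G - 1)
    gslope = take(G)
    beta = take(p)
    eta1 = take(K)
    eta2 = np.exp(np.clip(take(K), -30, 30))
    sigma = np.exp(np.clip(take(K), -30, 30))
    omega = np.ones(G)
    omega[_free_mask(G, spec._ref("ref_variance_class"))] = np.exp(
        np.clip(take(G - 1), -40, 30))
    return MLCMMParams(xi0, beta, gint, gslope, eta1, eta2, sigma, omega)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class MLCMMData:
    """Padded per-subject observation arrays for vectorised likelihoods.

    ``y``/``t``/``k`` are (N, M) with M the maximum number of outcome
    observations for any subject; ``mask`` marks real entries.  ``y`` holds
    the floor/ceiling-transformed outcomes (tCDRSB, nMMSE) to which the
    linear links apply.
    """

    subject_ids: np.ndarray
    X: np.ndarray        # (N, p) covariates
    y: np.ndarray        # (N, M)
    t: np.ndarray        # (N, M)
    k: np.ndarray        # (N, M) outcome index, int
    mask: np.ndarray     # (N, M) bool

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @classmethod
    def from_cohort(
        cls,
        cohort: CohortTable,
        covariates=DEFAULT_COVARIATES,
        mmse_lookup: np.ndarray | None = None,
    ) -> "MLCMMData":
        """Build the model dataset from a (pre-filtered) cohort.

        Subjects with a missing covariate are dropped with a warning; each
        visit contributes a tCDRSB observation and/or an nMMSE observation
        according to what was recorded.
        """
        lookup = load_mmse_lookup() if mmse_lookup is None else mmse_lookup
        X_df = design_matrix(cohort.subjects, covariates)
        complete = ~X_df.isna().any(axis=1)
        if not complete.all():
            warnings.warn(
                f"dropping {int((~complete).sum())} subjects with missing "
                "covariates from the MLCMM dataset"
            )
        subj_ids = cohort.subjects.loc[complete, "subject_id"].to_numpy()
        X = X_df.loc[complete].to_numpy(dtype=float)

        visits = cohort.visits[cohort.visits["subject_id"].isin(subj_ids)]
        tcd = transform_cdrsb(visits["cdrsb"].to_numpy(dtype=float))
        nmm = normalise_mmse(visits["mmse"].to_numpy(dtype=float), lookup)

        obs_y, obs_t, obs_k, obs_id = [], [], [], []
        times = visits["time_years"].to_numpy(dtype=float)
        vid = visits["subject_id"].to_numpy()
        for karr, kidx in ((tcd, 0), (nmm, 1)):
            keep = ~np.isnan(karr)
            obs_y.append(karr[keep])
            obs_t.append(times[keep])
            obs_k.append(np.full(keep.sum(), kidx, dtype=int))
            obs_id.append(vid[keep])
        obs_y = np.concatenate(obs_y)
        obs_t = np.concatenate(obs_t)
        obs_k = np.concatenate(obs_k)
        obs_id = np.concatenate(obs_id)

        order = {s: i for i, s in enumerate(subj_ids)}
        rows = np.array([order[s] for s in obs_id])
        counts = np.bincount(rows, minlength=len(subj_ids))
        if (counts == 0).any():
            bad = subj_ids[counts == 0]
            raise ValueError(
                f"{len(bad)} subjects have no usable outcome observation"
            )
        M = int(counts.max())
        N = len(subj_ids)
        y = np.zeros((N, M)); t = np.zeros((N, M))
        kk = np.zeros((N, M), dtype=int); mask = np.zeros((N, M), dtype=bool)
        slot = np.zeros(N, dtype=int)
        for r, yv, tv, kv in zip(rows, obs_y, obs_t, obs_k):
            j = slot[r]
            y[r, j] = yv; t[r, j] = tv; kk[r, j] = kv; mask[r, j] = True
            slot[r] += 1
        return cls(subj_ids, X, y, t, kk, mask)

    def subset(self, idx: np.ndarray) -> "MLCMMData":
        return MLCMMData(self.subject_ids[idx], self.X[idx], self.y[idx],
                         self.t[idx], self.k[idx], self.mask[idx])


def design_matrix(subjects: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Standard risk-factor design: age, male sex, education dummies
    (level 2 and 3 vs level 1), family history of AD, APOE e4 carriage."""
    cols = {}
    for name in covariates:
        if name == "age":
            cols[name] = subjects["age"].astype(float)
        elif name == "sex_male":
            cols[name] = _binary(subjects["sex"], {"male": 1.0, "female": 0.0})
        elif name == "edu2":
            cols[name] = (subjects["education_level"].astype(float) == 2) * 1.0
        elif name == "edu3":
            cols[name] = (subjects["education_level"].astype(float) == 3) * 1.0
        elif name == "family_history":
            cols[name] = _binary(subjects["family_history"], {"yes": 1.0, "no": 0.0})
        elif name == "apoe4":
            cols[name] = _binary(subjects["apoe4"], {"yes": 1.0, "no": 0.0})
        else:
            cols[name] = subjects[name].astype(float)
    return pd.DataFrame(cols, index=subjects.index)


def _binary(series: pd.Series, mapping: dict) -> pd.Series:
    if series.dtype == object:
        return series.map(mapping).astype(float)
    return series.astype(float)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def class_probabilities(xi0: np.ndarray) -> np.ndarray:
    """Softmax of the membership logits (reference entry 0)."""
    xi0 = np.asarray(xi0, dtype=float)
    z = xi0 - logsumexp(xi0)
    return np.exp(z)


def latent_mean(params: MLCMMParams, g: int, x: np.ndarray, t) -> np.ndarray:
    """Latent-process mean for class g: x'beta + gamma_g0 + gamma_g1 t."""
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing covariate in latent_mean")
    t = np.asarray(t, dtype=float)
    return float(x @ params.beta) + params.gamma_int[g] + params.gamma_slope[g] * t


def _class_logliks(params: MLCMMParams, data: MLCMMData) -> np.ndarray:
    """(N, G) matrix of per-subject class-conditional log-likelihoods.

    Closed form for the random-intercept-only covariance
    omega_g * 1 1' + diag(sigma_k^2) via Sherman-Morrison / matrix
    determinant lemma, on the observed-outcome scale (Jacobian of the
    linear links included).
    """
    mask = data.mask
    eta1 = params.eta1[data.k]
    eta2 = params.eta2[data.k]
    ytil = np.where(mask, (data.y - eta1) / eta2, 0.0)
    d = params.sigma[data.k] ** 2
    inv_d = np.where(mask, 1.0 / d, 0.0)
    sum_log_d = np.where(mask, np.log(d), 0.0).sum(axis=1)
    jac = np.where(mask, np.log(eta2), 0.0).sum(axis=1)
    m = mask.sum(axis=1)
    s = inv_d.sum(axis=1)
    base = data.X @ params.beta

    G = len(params.gamma_int)
    out = np.empty((data.n_subjects, G))
    for g in range(G):
        mu = base[:, None] + params.gamma_int[g] + params.gamma_slope[g] * data.t
        r = np.where(mask, ytil - mu, 0.0)
        b = (r * inv_d).sum(axis=1)
        a = (r * r * inv_d).sum(axis=1)
        w = params.omega[g]
        denom = 1.0 + w * s
        quad = a - w * b * b / denom
        out[:, g] = -0.5 * (m * _LOG2PI + sum_log_d + np.log(denom) + quad) - jac
    return out


def subject_class_loglik(params: MLCMMParams, data: MLCMMData, i: int, g: int) -> float:
    """Log density of subject i's observed outcomes under class g."""
    sub = data.subset(np.array([i]))
    return float(_class_logliks(params, sub)[0, g])


def log_likelihood(params: MLCMMParams, data: MLCMMData) -> float:
    """Observed-data mixture log-likelihood (log-sum-exp stabilised)."""
    ll = _class_logliks(params, data)
    logpi = params.xi0 - logsumexp(params.xi0)
    return float(logsumexp(ll + logpi[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MLCMMFit:
    """A fitted MLCMM: estimates, fit criteria and posterior classification."""

    spec: MLCMMSpec
    params: MLCMMParams
    loglik: float
    bic: float
    entropy: float
    n_params: int
    posterior: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    converged: bool
    n_starts_used: int
    seed: int | None
    covariate_means: np.ndarray
    start_status: list = field(default_factory=list, repr=False)
    _vec: np.ndarray | None = field(default=None, repr=False)


def _nll_factory(data: MLCMMData, spec: MLCMMSpec):
    def nll(vec: np.ndarray) -> float:
        params = _unpack(vec, spec)
        with np.errstate(over="ignore", invalid="ignore"):
            val = log_likelihood(params, data)
        if not np.isfinite(val):
            return 1e12
        return -val
    return nll


def _nll_grad_factory(data: MLCMMData, spec: MLCMMSpec):
    """Negative log-likelihood with its analytic gradient.

    Uses the mixture identity d/dθ log Σ_g π_g L_ig = Σ_g τ_ig d/dθ
    (log π_g + log L_ig) with responsibilities τ, and the closed-form
    derivatives of the compound-symmetry Gaussian density: with precision-
    weighted residuals e = Σ_g^{-1} r, the mean-parameter derivatives are
    linear in e, while the variance derivatives follow from
    d logN/dΣ = (e e' − Σ^{-1}) / 2 and Sherman–Morrison.
    """
    mask = data.mask
    m_per_k = [(mask & (data.k == kk)) for kk in range(spec.n_outcomes)]
    G = spec.n_classes
    free_mem = _free_mask(G, spec._ref("ref_membership_class"))
    free_int = _free_mask(G, spec._ref("ref_intercept_class"))
    free_var = _free_mask(G, spec._ref("ref_variance_class"))

    def nll_grad(vec: np.ndarray):
        p = _unpack(vec, spec)
        K = spec.n_outcomes
        with np.errstate(over="ignore", invalid="ignore"):
            eta1 = p.eta1[data.k]
            eta2 = p.eta2[data.k]
            ytil = np.where(mask, (data.y - eta1) / eta2, 0.0)
            d = p.sigma[data.k] ** 2
            inv_d = np.where(mask, 1.0 / d, 0.0)
            sum_log_d = np.where(mask, np.log(d), 0.0).sum(axis=1)
            jac = np.where(mask, np.log(eta2), 0.0).sum(axis=1)
            m = mask.sum(axis=1)
            s = inv_d.sum(axis=1)
            base = data.X @ p.beta

            ll = np.empty((data.n_subjects, G))
            r_all, b_all, D_all = [], [], []
            for g in range(G):
                mu = base[:, None] + p.gamma_int[g] + p.gamma_slope[g] * data.t
                r = np.where(mask, ytil - mu, 0.0)
                b = (r * inv_d).sum(axis=1)
                a = (r * r * inv_d).sum(axis=1)
                w = p.omega[g]
                D = 1.0 + w * s
                ll[:, g] = -0.5 * (m * _LOG2PI + sum_log_d + np.log(D)
                                   + a - w * b * b / D) - jac
                r_all.append(r); b_all.append(b); D_all.append(D)

            logpi = p.xi0 - logsumexp(p.xi0)
            lp = ll + logpi[None, :]
            per_subj = logsumexp(lp, axis=1)
            nll_val = -float(per_subj.sum())
            if not np.isfinite(nll_val):
                return 1e12, np.zeros_like(vec)
            tau = np.exp(lp - per_subj[:, None])   # (N, G)

            pi = np.exp(logpi)
            g_xi = tau.sum(axis=0) - data.n_subjects * pi      # (G,)
            g_int = np.zeros(G); g_slope = np.zeros(G); g_omega = np.zeros(G)
            g_beta = np.zeros(spec.n_covariates)
            g_eta1 = np.zeros(K); g_eta2 = np.zeros(K); g_sigma = np.zeros(K)
            for g in range(G):
                r, b, D = r_all[g], b_all[g], D_all[g]
                w = p.omega[g]
                e = np.where(mask, (r - (w * b / D)[:, None]) / d, 0.0)
                tg = tau[:, g]
                E = b / D
                g_int[g] = float((tg * E).sum())
                g_slope[g] = float((tg * (e * data.t).sum(axis=1)).sum())
                g_beta += data.X.T @ (tg * E)
                g_omega[g] = w * float(
                    (tg * 0.5 * (b * b / D ** 2 - s / D)).sum())
                for kk in range(K):
                    mk = m_per_k[kk]
                    g_eta1[kk] += float(
                        (tg * (e * mk).sum(axis=1)).sum()) / p.eta2[kk]
                    g_eta2[kk] += float((tg * (e * ytil * mk).sum(axis=1)).sum())
                    g_sigma[kk] += float((tg * (
                        (d * e * e - 1.0 + w / (D[:, None] * d)) * mk
                    ).sum(axis=1)).sum())
            g_eta2 -= np.array([mk.sum() for mk in m_per_k], dtype=float)

            grad = np.concatenate([
                g_xi[free_mem], g_int[free_int], g_slope, g_beta,
                g_eta1, g_eta2, g_sigma, g_omega[free_var],
            ])
            return nll_val, -grad
    return nll_grad


def _moment_start(data: MLCMMData, spec: MLCMMSpec) -> MLCMMParams:
    """Single-class moment start: links absorb outcome location/scale."""
    G, p, K = spec.n_classes, spec.n_covariates, spec.n_outcomes
    eta1 = np.zeros(K); eta2 = np.ones(K)
    for kk in range(K):
        vals = data.y[data.mask & (data.k == kk)]
        eta1[kk] = np.mean(vals) if vals.size else 0.0
        sd = np.std(vals) if vals.size > 1 else 1.0
        eta2[kk] = max(sd, 1e-3)
    return MLCMMParams(
        xi0=np.zeros(G), beta=np.zeros(p), gamma_int=np.zeros(G),
        gamma_slope=np.zeros(G), eta1=eta1, eta2=eta2,
        sigma=np.full(K, 0.5), omega=np.ones(G),
    )


def _perturb(params: MLCMMParams, spec: MLCMMSpec, rng: np.random.Generator,
             scale: float) -> MLCMMParams:
    out = params.copy()
    G = spec.n_classes
    out.gamma_int = out.gamma_int + rng.normal(0, 1.5 * scale, G)
    out.gamma_int[spec._ref("ref_intercept_class")] = 0.0
    out.gamma_slope = out.gamma_slope + rng.normal(0, 0.5 * scale, G)
    out.xi0 = out.xi0 + rng.normal(0, 0.5 * scale, G)
    out.xi0[spec._ref("ref_membership_class")] = 0.0
    out.eta1 = out.eta1 * (1 + rng.normal(0, 0.05 * scale, len(out.eta1)))
    out.eta2 = out.eta2 * np.exp(rng.normal(0, 0.2 * scale, len(out.eta2)))
    out.sigma = out.sigma * np.exp(rng.normal(0, 0.3 * scale, len(out.sigma)))
    out.omega = out.omega * np.exp(rng.normal(0, 0.5 * scale, G))
    out.omega[spec._ref("ref_variance_class")] = 1.0
    return out


def fit(
    data: MLCMMData,
    spec: MLCMMSpec,
    n_starts: int = 30,
    tol: float = 1e-11,
    max_iter: int = 500,
    seed: int | None = None,
) -> MLCMMFit:
    """Maximum-likelihood fit by multi-start quasi-Newton optimisation.

    The first start perturbs a single-class fit; the remainder are random
    perturbations of the moment start.  Deterministic given ``seed``.
    Raises if every start fails to produce a finite objective.
    """
    if data.n_subjects == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    nll = _nll_grad_factory(data, spec)

    starts: list[MLCMMParams] = []
    if spec.n_classes > 1:
        sub_spec = replace(spec, n_classes=1, ref_intercept_class=0,
                           ref_variance_class=0, ref_membership_class=0)
        base_fit = fit(data, sub_spec, n_starts=2, tol=tol,
                       max_iter=max_iter, seed=rng.integers(2 ** 31))
        bp = base_fit.params
        tmpl = MLCMMParams(
            xi0=np.zeros(spec.n_classes), beta=bp.beta.copy(),
            gamma_int=np.zeros(spec.n_classes),
            gamma_slope=np.repeat(bp.gamma_slope, spec.n_classes),
            eta1=bp.eta1.copy(), eta2=bp.eta2.copy(), sigma=bp.sigma.copy(),
            omega=np.ones(spec.n_classes),
        )
        starts.append(_perturb(tmpl, spec, rng, scale=1.0))
        for _ in range(n_starts - 1):
            starts.append(_perturb(tmpl, spec, rng, scale=rng.uniform(0.5, 2.0)))
    else:
        tmpl = _moment_start(data, spec)
        starts.append(tmpl)
        for _ in range(n_starts - 1):
            starts.append(_perturb(tmpl, spec, rng, scale=1.0))

    opts = {"maxiter": max_iter, "ftol": tol, "gtol": 1e-7, "maxfun": 200000}
    best_vec, best_val, best_ok, status = None, np.inf, False, []
    for s_idx, start in enumerate(starts):
        x0 = _pack(start, spec)
        try:
            res = minimize(nll, x0, method="L-BFGS-B", jac=True, options=opts)
        except Exception as exc:  # pragma: no cover - optimiser blow-up
            status.append({"start": s_idx, "converged": False, "error": str(exc)})
            continue
        status.append({"start": s_idx, "converged": bool(res.success),
                       "nll": float(res.fun)})
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_vec, best_ok = float(res.fun), res.x, bool(res.success)
    if best_vec is None:
        raise RuntimeError(f"all starts failed: {status}")

    # polish: restarting L-BFGS at the incumbent resets its curvature
    # approximation; a near-zero ftol forces it through the flat tail of
    # the likelihood so the last digits are tight
    polish_opts = {**opts, "ftol": 1e-14, "gtol": 1e-8}
    for _ in range(3):
        res = minimize(nll, best_vec, method="L-BFGS-B", jac=True,
                       options=polish_opts)
        if not (np.isfinite(res.fun) and res.fun < best_val - 1e-10):
            best_ok = best_ok or bool(res.success)
            break
        best_val, best_vec, best_ok = float(res.fun), res.x, bool(res.success)

    params = _unpack(best_vec, spec)
    loglik = -best_val
    posterior = posterior_from_params(params, data)
    labels = hard_assign(posterior)
    mets = metrics_from(loglik, posterior, spec, data.n_subjects)
    return MLCMMFit(
        spec=spec, params=params, loglik=loglik, bic=mets["bic"],
        entropy=mets["entropy"], n_params=mets["n_params"],
        posterior=posterior, labels=labels, subject_ids=data.subject_ids,
        converged=best_ok,
        n_starts_used=len(starts), seed=seed,
        covariate_means=data.X.mean(axis=0), start_status=status,
        _vec=best_vec,
    )


# ---------------------------------------------------------------------------
# posterior classification and fit criteria
# ---------------------------------------------------------------------------

def posterior_from_params(params: MLCMMParams, data: MLCMMData) -> np.ndarray:
    ll = _class_logliks(params, data)
    logpi = params.xi0 - logsumexp(params.xi0)
    lp = ll + logpi[None, :]
    lp -= logsumexp(lp, axis=1, keepdims=True)
    return np.exp(lp)


def posterior_class_probs(fit_result: MLCMMFit, data: MLCMMData) -> np.ndarray:
    """N x G posterior class-membership probabilities; rows sum to 1."""
    return posterior_from_params(fit_result.params, data)


def hard_assign(posterior: np.ndarray) -> np.ndarray:
    """Row-wise argmax; ties broken toward the lowest class index."""
    posterior = np.asarray(posterior, dtype=float)
    labels = np.argmax(posterior, axis=1)
    mx = posterior[np.arange(len(labels)), labels]
    n_ties = int(((posterior == mx[:, None]).sum(axis=1) > 1).sum())
    if n_ties:
        warnings.warn(f"{n_ties} posterior ties broken toward the lowest class")
    return labels


def relative_entropy(posterior: np.ndarray) -> float:
    """1 - normalised Shannon entropy of the posterior memberships.

    1 for a crisp classification, 0 for uniform posteriors; defined as 1
    when G = 1.
    """
    N, G = posterior.shape
    if G == 1:
        return 1.0
    p = np.clip(posterior, 1e-300, 1.0)
    H = -(posterior * np.log(p)).sum()
    return float(1.0 - H / (N * np.log(G)))


def metrics_from(loglik: float, posterior: np.ndarray, spec: MLCMMSpec,
                 N: int) -> dict:
    p = n_free_params(spec)
    return {
        "bic": float(-2.0 * loglik + p * np.log(N)),
        "entropy": relative_entropy(posterior),
        "n_params": p,
    }


def metrics(fit_result: MLCMMFit, N: int | None = None) -> dict:
    """BIC, relative entropy and free-parameter count for a fitted model."""
    n = len(fit_result.posterior) if N is None else N
    return metrics_from(fit_result.loglik, fit_result.posterior,
                        fit_result.spec, n)


# ---------------------------------------------------------------------------
# standard errors, trajectories, prediction
# ---------------------------------------------------------------------------

def _numerical_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x0)
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x0 + ei + ej); fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej); fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _gradient_hessian(grad_f, x0: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian by central differences of an analytic gradient."""
    n = len(x0)
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        _, gp = grad_f(x0 + ei)
        _, gm = grad_f(x0 - ei)
        H[i] = (gp - gm) / (2 * h[i])
    return 0.5 * (H + H.T)


def observed_information(fit_result: MLCMMFit, data: MLCMMData) -> np.ndarray:
    """Covariance of the free-parameter vector (unconstrained scale) from
    the numerically differentiated observed information."""
    H = _gradient_hessian(_nll_grad_factory(data, fit_result.spec),
                          fit_result._vec)
    # symmetrise and regularise minimally before inversion
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov


def _free_param_names(spec: MLCMMSpec) -> list[str]:
    G, p, K = spec.n_classes, spec.n_covariates, spec.n_outcomes
    names = []
    names += [f"xi0[{g}]" for g in range(G) if g != spec._ref("ref_membership_class")]
    names += [f"gamma_int[{g}]" for g in range(G) if g != spec._ref("ref_intercept_class")]
    names += [f"gamma_slope[{g}]" for g in range(G)]
    names += [f"beta[{j}]" for j in range(p)]
    names += [f"eta1[{k}]" for k in range(K)]
    names += [f"eta2[{k}]" for k in range(K)]
    names += [f"sigma[{k}]" for k in range(K)]
    names += [f"omega[{g}]" for g in range(G) if g != spec._ref("ref_variance_class")]
    return names


def standard_errors(fit_result: MLCMMFit, data: MLCMMData) -> pd.DataFrame:
    """Natural-scale estimates and delta-method standard errors.

    Log-transformed parameters (eta2, sigma, omega) get SE_natural =
    SE_log * value.
    """
    cov = observed_information(fit_result, data)
    se_u = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    vec = fit_result._vec
    names = _free_param_names(fit_result.spec)
    est, se = [], []
    for name, v, s in zip(names, vec, se_u):
        if name.startswith(("eta2", "sigma", "omega")):
            est.append(np.exp(v)); se.append(np.exp(v) * s)
        else:
            est.append(v); se.append(s)
    return pd.DataFrame({"parameter": names, "estimate": est, "se": se})


@dataclass
class LatentTrajectory:
    """Predicted class trajectory on the latent and outcome scales."""

    class_index: int
    times: np.ndarray
    latent_mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    outcome_curves: dict


def predict_trajectory(
    fit_result: MLCMMFit,
    data: MLCMMData,
    g: int,
    times: np.ndarray,
    profile: np.ndarray | None = None,
    cov: np.ndarray | None = None,
    mmse_lookup: np.ndarray | None = None,
) -> LatentTrajectory:
    """Latent-scale class trajectory at a covariate profile with a
    delta-method 95% band, plus back-transformed outcome-scale curves.

    ``profile`` defaults to the covariate means of the fitting data;
    ``cov`` may carry a precomputed free-parameter covariance.
    """
    from .data_prep import inverse_transform_cdrsb

    spec = fit_result.spec
    params = fit_result.params
    times = np.asarray(times, dtype=float)
    x = fit_result.covariate_means if profile is None else np.asarray(profile, float)
    lat = latent_mean(params, g, x, times)

    if cov is None:
        cov = observed_information(fit_result, data)
    names = _free_param_names(spec)
    n_free = len(names)
    grad = np.zeros((len(times), n_free))
    for j, name in enumerate(names):
        if name == f"gamma_int[{g}]":
            grad[:, j] = 1.0
        elif name == f"gamma_slope[{g}]":
            grad[:, j] = times
        elif name.startswith("beta["):
            idx = int(name[5:-1])
            grad[:, j] = x[idx]
    var = np.einsum("tj,jk,tk->t", grad, cov, grad)
    half = 1.959963984540054 * np.sqrt(np.clip(var, 0, np.inf))

    tcd = params.eta1[0] + params.eta2[0] * lat
    nmm = params.eta1[1] + params.eta2[1] * lat
    curves = {
        "tcdrsb": tcd,
        "nmmse": nmm,
        "cdrsb": inverse_transform_cdrsb(np.clip(tcd, -5.19, 5.19)),
    }
    return LatentTrajectory(g, times, lat, lat - half, lat + half, curves)


def predict_class_newdata(
    fit_result: MLCMMFit, newdata: MLCMMData
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior classification of unseen subjects under fitted parameters.

    Returns (subject_ids, labels, posterior) for subjects with complete
    covariates and at least one outcome observation; others are skipped
    with a warning.
    """
    ok = ~np.isnan(newdata.X).any(axis=1) & (newdata.mask.sum(axis=1) > 0)
    if not ok.all():
        warnings.warn(f"skipping {int((~ok).sum())} subjects with missing inputs")
    sub = newdata.subset(np.where(ok)[0])
    post = posterior_from_params(fit_result.params, sub)
    return sub.subject_ids, hard_assign(post), post


# ---------------------------------------------------------------------------
# class relabelling under the reference conventions
# ---------------------------------------------------------------------------

def relabel_classes(params: MLCMMParams, perm, spec: MLCMMSpec) -> MLCMMParams:
    """Re-express parameters with classes reordered as ``perm`` (new class g
    takes old class perm[g]) and the reference conventions re-imposed.

    The model is equivariant under this map: relabelling plus the latent
    rescale (to restore omega_ref = 1) and intercept shift (to restore
    gamma_int_ref = 0, absorbed into eta1) leaves the likelihood unchanged.
    """
    perm = np.asarray(perm, dtype=int)
    out = params.copy()
    out.xi0 = params.xi0[perm].copy()
    out.gamma_int = params.gamma_int[perm].copy()
    out.gamma_slope = params.gamma_slope[perm].copy()
    out.omega = params.omega[perm].copy()

    w_ref = out.omega[spec._ref("ref_variance_class")]
    s = np.sqrt(w_ref)
    out.omega = out.omega / w_ref
    out.beta = out.beta / s
    out.gamma_int = out.gamma_int / s
    out.gamma_slope = out.gamma_slope / s
    out.sigma = out.sigma / s
    out.eta2 = out.eta2 * s

    c = out.gamma_int[spec._ref("ref_intercept_class")]
    out.gamma_int = out.gamma_int - c
    out.eta1 = out.eta1 + out.eta2 * c

    out.xi0 = out.xi0 - out.xi0[spec._ref("ref_membership_class")]
    return out
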