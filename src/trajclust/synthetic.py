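"""Synthetic longitudinal cohorts with the structure both modelling stages assume.

The generator emulates a multi-centre pre-dementia cohort: latent trajectory
classes drive two noisy cognitive outcomes (CDRSB, MMSE) through linear
links on a shared latent process with class-specific random intercepts;
biomarker clusters with Bernoulli/Gaussian profiles couple to the classes
through cluster-conditional class probabilities.  Visits follow the
(0, 0.5, 1, 2, 3)-year schedule with monotone attrition; MMSE is not
collected at the 6-months visit; outcome and covariate missingness is
missing-at-random.  Default parameter values reproduce the fitted 4-class /
7-cluster structure of the motivating cohort study; crisp presets provide
ground-truth test beds for class and cluster recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import data_prep
from .data_prep import CohortTable, inverse_transform_cdrsb, load_mmse_lookup
from .profile_regression import ProfileDataset

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_cohort", "scenario",
           "build_profile_dataset", "SCENARIOS"]


def _t2(*vals):
    return np.array(vals, dtype=float)


@dataclass
class SyntheticConfig:
    """Generative parameters.  Defaults are the fitted 4-class trajectory
    model and 7-cluster biomarker-profile structure of the motivating
    study; the class-membership logits, class intercepts/slopes, covariate
    effects, link parameters, error variances and proportionality factors
    are its published estimates, and the cluster profiles its published
    posterior means."""

    n_subjects: int = 1543
    seed: int | None = None

    # --- trajectory-class model (latent process) ---
    xi0: np.ndarray = field(default_factory=lambda: _t2(1.30, -1.04, -0.87, 0.0))
    gamma_int: np.ndarray = field(default_factory=lambda: _t2(0.0, -2.33, -0.65, -3.14))
    gamma_slope: np.ndarray = field(default_factory=lambda: _t2(-0.0040, 2.43, -1.58, 0.16))
    beta: np.ndarray = field(default_factory=lambda: _t2(-0.0033, -0.015, 0.022, 0.043, 0.016, -0.021))
    eta1: np.ndarray = field(default_factory=lambda: _t2(5.31, 87.96))
    eta2: np.ndarray = field(default_factory=lambda: _t2(0.73, 3.80))
    sigma: np.ndarray = field(default_factory=lambda: np.sqrt(_t2(0.531, 3.527)))
    omega: np.ndarray = field(default_factory=lambda: _t2(0.0004, 0.397, 0.957, 1.0))

    # --- visit process ---
    visit_times: np.ndarray = field(default_factory=lambda: _t2(0.0, 0.5, 1.0, 2.0, 3.0))
    retention: np.ndarray = field(default_factory=lambda: _t2(0.857, 0.758, 0.333, 0.225))
    mmse_missing_times: tuple = (0.5,)
    p_extra_missing_mmse: float = 0.02
    p_missing_cdrsb: float = 0.002

    # --- baseline risk factors ---
    age_mean: float = 65.4
    age_sd: float = 7.4
    age_min: float = 50.0
    p_female: float = 0.564
    edu_probs: np.ndarray = field(default_factory=lambda: _t2(0.373, 0.250, 0.377))
    p_family_history: float = 0.655
    p_apoe4: float = 0.375
    p_apoe_missing: float = 0.0197

    # --- biomarker clusters ---
    cluster_weights: np.ndarray = field(default_factory=lambda: _t2(
        0.373, 0.071, 0.265, 0.147, 0.053, 0.047, 0.044))
    # columns: pTau/Abeta, MTA, FSD, FSPV, ARWMC-combined positivity
    cluster_bern: np.ndarray = field(default_factory=lambda: np.array([
        [0.113, 0.096, 0.079, 0.269, 0.143],
        [0.166, 0.575, 0.278, 0.567, 0.357],
        [0.145, 0.200, 0.195, 0.436, 0.287],
        [0.353, 0.337, 0.135, 0.405, 0.202],
        [0.553, 0.810, 0.380, 0.675, 0.524],
        [0.308, 0.309, 0.276, 0.529, 0.319],
        [0.228, 0.247, 0.157, 0.376, 0.240],
    ]))
    # columns: HV, VV, HV rate, VV rate (standardised scale)
    cluster_gauss_mean: np.ndarray = field(default_factory=lambda: np.array([
        [0.549, -0.674, 0.362, -0.463],
        [-0.706, 1.590, 0.047, 0.321],
        [-0.111, 0.101, -0.066, -0.042],
        [-0.300, -0.063, -0.166, 0.020],
        [-1.229, 1.583, -1.093, 1.558],
        [-0.354, 0.287, 0.000, 0.407],
        [0.025, -0.109, 0.026, -0.004],
    ]))
    #: correlation between each volume and its own rate of change
    volume_rate_corr: float = 0.3
    # rows: clusters; columns: trajectory classes
    class_probs_given_cluster: np.ndarray = field(default_factory=lambda: np.array([
        [0.917, 0.040, 0.038, 0.005],
        [0.791, 0.133, 0.038, 0.039],
        [0.976, 0.015, 0.006, 0.003],
        [0.010, 0.040, 0.009, 0.941],
        [0.101, 0.024, 0.154, 0.721],
        [0.064, 0.177, 0.731, 0.028],
        [0.248, 0.464, 0.173, 0.115],
    ]))
    # raw scales for HV, VV, HV rate, VV rate (mm^3, mm^3/year)
    raw_means: np.ndarray = field(default_factory=lambda: _t2(5793.0, 32997.0, -23.8, 1274.0))
    raw_sds: np.ndarray = field(default_factory=lambda: _t2(705.0, 17687.0, 88.7, 1264.0))
    missing_rates: dict = field(default_factory=lambda: {
        "csf": 0.021, "radiology": 0.008,
        "hv_baseline": 0.039, "vv_baseline": 0.107, "volume_last": 0.05,
    })
    #: inconclusive (0.5) share among MTA-negative reads
    p_mta_inconclusive: float = 0.32

    def validate(self) -> None:
        G = len(self.xi0)
        C = len(self.cluster_weights)
        checks = {
            "gamma_int": len(self.gamma_int) == G,
            "gamma_slope": len(self.gamma_slope) == G,
            "omega": len(self.omega) == G,
            "eta1/eta2/sigma": len(self.eta1) == len(self.eta2) == len(self.sigma) == 2,
            "cluster_bern": self.cluster_bern.shape == (C, 5),
            "cluster_gauss_mean": self.cluster_gauss_mean.shape == (C, 4),
            "class_probs_given_cluster": self.class_probs_given_cluster.shape == (C, G),
            "visit_times": np.all(np.diff(self.visit_times) > 0),
            "retention": len(self.retention) == len(self.visit_times) - 1,
            "edu_probs": abs(self.edu_probs.sum() - 1) < 1e-6,
            "cluster_weights": abs(self.cluster_weights.sum() - 1) < 0.01,
        }
        for path, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid synthetic config field: {path}")
        for path, arr in (("cluster_bern", self.cluster_bern),
                          ("class_probs_given_cluster", self.class_probs_given_cluster),
                          ("retention", self.retention),
                          ("edu_probs", self.edu_probs)):
            if np.any(np.asarray(arr) < 0) or np.any(np.asarray(arr) > 1):
                raise ValueError(f"invalid synthetic config field: {path}: "
                                 "probabilities must lie in [0, 1]")
        rows = self.class_probs_given_cluster.sum(axis=1)
        if np.any(np.abs(rows - 1) > 0.01):
            raise ValueError("invalid synthetic config field: "
                             "class_probs_given_cluster rows must sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.xi0)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_weights)


@dataclass
class SyntheticTruth:
    """Ground truth per subject: generating class, cluster and random intercept."""

    table: pd.DataFrame  # subject_id, true_class, true_cluster, random_intercept

    @property
    def classes(self) -> np.ndarray:
        return self.table["true_class"].to_numpy()

    @property
    def clusters(self) -> np.ndarray:
        return self.table["true_cluster"].to_numpy()


def generate_cohort(config: SyntheticConfig, seed: int | None = None
                    ) -> tuple[CohortTable, ProfileDataset, SyntheticTruth]:
    """Draw a full synthetic cohort; reproducible given the seed.

    Classes are drawn from softmax(xi0); clusters from the class-conditional
    table obtained by Bayes inversion of the cluster-conditional class
    probabilities with the configured cluster weights.  Outcomes are built
    on the transformed scales and back-transformed to the instruments' grids
    (CDRSB to the 0.5-step grid on [0, 18]; MMSE to integers on [0, 30] via
    the normalisation lookup).  Dropout is monotone: once a visit is missed
    no later visit occurs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    G, C = config.n_classes, config.n_clusters
    lookup = load_mmse_lookup()

    # latent class, then cluster | class by Bayes inversion
    pi = np.exp(config.xi0 - config.xi0.max())
    pi /= pi.sum()
    classes = rng.choice(G, size=n, p=pi)
    joint = config.class_probs_given_cluster * config.cluster_weights[:, None]
    cluster_given_class = joint / joint.sum(axis=0, keepdims=True)  # (C, G)
    u = rng.random(n)
    cum = np.cumsum(cluster_given_class, axis=0)  # (C, G)
    clusters = (u[None, :] > cum[:, classes]).sum(axis=0)

    # baseline risk factors
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    for _ in range(20):
        low = age < config.age_min
        if not low.any():
            break
        age[low] = rng.normal(config.age_mean, config.age_sd, size=low.sum())
    age = np.clip(age, config.age_min, None)
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    edu = rng.choice([1, 2, 3], size=n, p=config.edu_probs)
    fam = np.where(rng.random(n) < config.p_family_history, "yes", "no")
    apoe = np.where(rng.random(n) < config.p_apoe4, "yes", "no").astype(object)
    apoe[rng.random(n) < config.p_apoe_missing] = np.nan

    X = np.column_stack([
        age, (sex == "male").astype(float), (edu == 2).astype(float),
        (edu == 3).astype(float), (fam == "yes").astype(float),
        np.where(pd.isna(apoe), 0.0, (apoe == "yes").astype(float)),
    ])

    upsilon = rng.normal(0.0, np.sqrt(config.omega[classes]))

    # visit attendance: monotone dropout
    n_visits = len(config.visit_times)
    attend = np.ones((n, n_visits), dtype=bool)
    for v in range(1, n_visits):
        stay = rng.random(n) < config.retention[v - 1]
        attend[:, v] = attend[:, v - 1] & stay

    # outcomes on the transformed scales, then instrument grids
    subject_ids = np.array([f"S{i:05d}" for i in range(n)])
    rows = []
    fixed = X @ config.beta
    for v, t in enumerate(config.visit_times):
        here = attend[:, v]
        lam = (fixed + config.gamma_int[classes]
               + config.gamma_slope[classes] * t + upsilon)
        tcd = config.eta1[0] + config.eta2[0] * (lam + rng.normal(0, config.sigma[0], n))
        nmm = config.eta1[1] + config.eta2[1] * (lam + rng.normal(0, config.sigma[1], n))
        cdrsb = np.clip(
            np.round(inverse_transform_cdrsb(np.clip(tcd, -5.198, 5.198)) * 2) / 2,
            0.0, 18.0)
        mmse = data_prep.inverse_normalise_mmse(np.clip(nmm, 0.0, 100.0), lookup)
        miss_m = (t in config.mmse_missing_times) | \
            (rng.random(n) < config.p_extra_missing_mmse)
        miss_c = rng.random(n) < config.p_missing_cdrsb
        cdrsb = np.where(miss_c, np.nan, cdrsb)
        mmse = np.where(miss_m, np.nan, mmse)
        both_missing = np.isnan(cdrsb) & np.isnan(mmse)
        cdrsb = np.where(both_missing, np.clip(np.round(
            inverse_transform_cdrsb(np.clip(tcd, -5.198, 5.198)) * 2) / 2, 0, 18),
            cdrsb)  # keep every attended visit usable
        for i in np.where(here)[0]:
            rows.append((subject_ids[i], t, cdrsb[i], mmse[i]))
    visits = pd.DataFrame(rows, columns=["subject_id", "time_years", "cdrsb", "mmse"])

    # biomarkers from the cluster profile
    flags = (rng.random((n, 5)) < config.cluster_bern[clusters]).astype(float)
    rho = config.volume_rate_corr
    cov = np.eye(4)
    cov[0, 2] = cov[2, 0] = rho   # HV ~ HV rate
    cov[1, 3] = cov[3, 1] = rho   # VV ~ VV rate
    z = config.cluster_gauss_mean[clusters] + \
        rng.multivariate_normal(np.zeros(4), cov, size=n)
    raw = config.raw_means[None, :] + config.raw_sds[None, :] * z
    hv0, vv0, hv_rate, vv_rate = raw.T
    hv0 = np.clip(hv0, 100.0, None)
    vv0 = np.clip(vv0, 1000.0, None)

    last_t = np.array([
        config.visit_times[np.where(attend[i])[0][-1]] for i in range(n)])
    has_follow = last_t > 0
    t_last = np.where(has_follow, last_t, np.nan)
    hv_last = np.where(has_follow, hv0 + hv_rate * last_t, np.nan)
    vv_last = np.where(has_follow, vv0 + vv_rate * last_t, np.nan)

    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "age": age, "sex": sex, "education_level": edu,
        "family_history": fam, "apoe4": apoe,
        "cdr_global": rng.choice([0.0, 0.5], size=n, p=[0.78, 0.22]),
    })
    _raw_biomarkers(subjects, flags, rng, config)
    subjects["hv_baseline"] = hv0
    subjects["vv_baseline"] = vv0
    subjects["hv_last"] = hv_last
    subjects["vv_last"] = vv_last
    subjects["t_last_volume"] = t_last

    # MAR covariate missingness
    mr = config.missing_rates
    def _blank(cols, rate):
        if rate <= 0:
            return
        hit = rng.random(n) < rate
        for c in cols:
            subjects.loc[hit, c] = np.nan
    _blank(["ptau_abeta"], mr.get("csf", 0.0))
    _blank(["mta_avg", "fsd", "fspv", *data_prep.ARWMC_COLUMNS],
           mr.get("radiology", 0.0))
    _blank(["hv_baseline"], mr.get("hv_baseline", 0.0))
    _blank(["vv_baseline"], mr.get("vv_baseline", 0.0))
    _blank(["hv_last", "vv_last"], mr.get("volume_last", 0.0))

    cohort = CohortTable(subjects, visits.reset_index(drop=True))
    truth = SyntheticTruth(pd.DataFrame({
        "subject_id": subject_ids, "true_class": classes,
        "true_cluster": clusters, "random_intercept": upsilon,
    }))
    profiles = build_profile_dataset(cohort, classes, G)
    return cohort, profiles, truth


def _raw_biomarkers(subjects: pd.DataFrame, flags: np.ndarray,
                    rng: np.random.Generator, config: SyntheticConfig) -> None:
    """Raw biomarker scores consistent with the drawn binary pathology flags."""
    n = len(subjects)
    ad, mta, fsd, fspv, arwmc = flags.T
    cut = data_prep.PTAU_ABETA_CUTOFF
    subjects["ptau_abeta"] = np.where(
        ad == 1, rng.uniform(cut + 0.001, 0.12, n), rng.uniform(0.004, cut, n))
    subjects["mta_avg"] = np.where(
        mta == 1, rng.choice([1.0, 1.5, 2.0], n, p=[0.6, 0.3, 0.1]),
        np.where(rng.random(n) < config.p_mta_inconclusive, 0.5, 0.0))
    subjects["fsd"] = np.where(
        fsd == 1, rng.choice([2, 3], n, p=[0.8, 0.2]),
        rng.choice([0, 1], n, p=[0.7, 0.3])).astype(float)
    subjects["fspv"] = np.where(
        fspv == 1, rng.choice([1, 2, 3], n, p=[0.6, 0.3, 0.1]), 0).astype(float)
    counts = np.where(
        arwmc == 1, rng.choice([3, 4, 5], n, p=[0.6, 0.3, 0.1]),
        rng.choice([0, 1, 2], n, p=[0.4, 0.35, 0.25]))
    region_scores = np.zeros((n, 5))
    for i in range(n):
        pos = rng.choice(5, size=counts[i], replace=False)
        region_scores[i, pos] = rng.choice([1, 2], size=counts[i], p=[0.7, 0.3])
    for j, col in enumerate(data_prep.ARWMC_COLUMNS):
        subjects[col] = region_scores[:, j]


def build_profile_dataset(cohort: CohortTable, outcome: np.ndarray | None,
                          n_classes: int) -> ProfileDataset:
    """Assemble the clustering-stage dataset from a cohort via the standard
    derivations (flags, standardised volumes and annualised rates)."""
    derived = data_prep.derive_profiles(cohort)
    w_bin = derived[["ad_positive", "mta_flag", "fsd_flag", "fspv_flag",
                     "arwmc_flag"]].to_numpy(dtype=float)
    w_cont = derived[["hv", "vv", "hv_rate", "vv_rate"]].to_numpy(dtype=float)
    return ProfileDataset(
        subject_ids=cohort.subjects["subject_id"].to_numpy(),
        y=None if outcome is None else np.asarray(outcome, dtype=int),
        n_classes=n_classes, w_bin=w_bin, w_cont=w_cont,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _crisp_classes_config(**over) -> SyntheticConfig:
    # classes sit mid-scale on both instruments so that the 0.5-step CDRSB
    # grid and the MMSE lookup are dense relative to the measurement noise
    cfg = SyntheticConfig(
        n_subjects=over.pop("n_subjects", 500),
        xi0=_t2(0.4, 0.0),
        gamma_int=_t2(-3.5, -9.5),
        gamma_slope=_t2(0.3, -0.4),
        omega=_t2(0.25, 1.0),
        sigma=_t2(1.0, 1.2),
        retention=_t2(0.9, 0.85, 0.8, 0.75),
        p_apoe_missing=0.0,
        cluster_weights=_t2(0.6, 0.4),
        cluster_bern=np.array([[0.1] * 5, [0.9] * 5]),
        cluster_gauss_mean=np.array([[-1.5, -1.5, 1.5, 1.5],
                                     [1.5, 1.5, -1.5, -1.5]]),
        class_probs_given_cluster=np.array([[0.95, 0.05], [0.05, 0.95]]),
        missing_rates={},
    )
    return replace(cfg, **over)


def _crisp_clusters_config(**over) -> SyntheticConfig:
    cfg = SyntheticConfig(
        n_subjects=over.pop("n_subjects", 300),
        xi0=_t2(0.0, 0.0, 0.0),
        gamma_int=_t2(-2.0, -6.0, -10.0),
        gamma_slope=_t2(0.3, -0.3, 0.1),
        omega=_t2(0.3, 0.5, 1.0),
        sigma=_t2(1.0, 1.2),
        retention=_t2(0.9, 0.85, 0.8, 0.75),
        p_apoe_missing=0.0,
        cluster_weights=_t2(1 / 3, 1 / 3, 1 / 3),
        cluster_bern=np.array([
            [0.05, 0.05, 0.05, 0.05, 0.05],
            [0.95, 0.95, 0.95, 0.95, 0.95],
            [0.95, 0.05, 0.95, 0.05, 0.5],
        ]),
        cluster_gauss_mean=np.array([
            [-2.0, -2.0, 2.0, 2.0],
            [2.0, 2.0, -2.0, -2.0],
            [2.0, -2.0, 2.0, -2.0],
        ]),
        class_probs_given_cluster=np.array([
            [0.96, 0.02, 0.02],
            [0.02, 0.96, 0.02],
            [0.02, 0.02, 0.96],
        ]),
        missing_rates={},
    )
    return replace(cfg, **over)


def _null_config(**over) -> SyntheticConfig:
    cfg = SyntheticConfig(
        n_subjects=over.pop("n_subjects", 200),
        xi0=_t2(0.0),
        gamma_int=_t2(0.0),
        gamma_slope=_t2(0.0),
        omega=_t2(1.0),
        p_apoe_missing=0.0,
        cluster_weights=_t2(1.0),
        cluster_bern=np.array([[0.3] * 5]),
        cluster_gauss_mean=np.zeros((1, 4)),
        class_probs_given_cluster=np.array([[1.0]]),
        missing_rates={},
    )
    return replace(cfg, **over)


SCENARIOS = {
    "epad_like": lambda **over: replace(SyntheticConfig(), **over),
    "crisp_classes": _crisp_classes_config,
    "crisp_clusters": _crisp_clusters_config,
    "null_structure": _null_config,
    "small_test": lambda **over: _crisp_classes_config(
        n_subjects=over.pop("n_subjects", 60),
        retention=_t2(1.0, 1.0, 1.0, 1.0), **over),
}


def scenario(name: str, **overrides) -> SyntheticConfig:
    """Documented preset configurations.

    ``epad_like`` is the full-scale default structure (n = 1,543);
    ``crisp_classes`` / ``crisp_clusters`` are well-separated recovery test
    beds; ``null_structure`` has one class and one cluster;
    ``small_test`` is a tiny crisp cohort with no attrition.
    """
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    return SCENARIOS[name](**overrides)
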