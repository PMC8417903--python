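"""Stability validation by repeated stratified sub-setting.

The cohort is repeatedly split in half (stratified by number of visits,
random equal-probability allocation within each stratum).  The two-stage
pipeline is re-run on each subset; class validity is assessed by
cross-predicting trajectory-class membership between subsets (Cohen's kappa
and adjusted Rand index against in-sample assignments, after Hungarian
label matching) and by comparing subset assignments with the full-data
model.  Cluster validity compares each subset's consensus dissimilarity
matrix and representative clustering with the full-data analysis restricted
to the subset, and held-out predicted dissimilarities/clusterings with the
corresponding full-data blocks and subset analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster_summary as cs
from . import mlcmm
from . import profile_regression as pr
from .data_prep import CohortTable

__all__ = [
    "SplitPlan",
    "StabilityReport",
    "make_splits",
    "class_stability",
    "cluster_stability",
]


@dataclass
class SplitPlan:
    """Reproducible half/half splits stratified by number of visits."""

    splits: list  # list of (idx_a, idx_b) subject-index arrays
    subject_ids: np.ndarray
    n_splits: int
    seed: int | None


@dataclass
class StabilityReport:
    """Per-comparison agreement statistics with their summary."""

    comparisons: pd.DataFrame
    summary: dict = field(default_factory=dict)


def make_splits(cohort: CohortTable, n_splits: int = 10,
                seed: int | None = None) -> SplitPlan:
    """Stratify subjects by visit count, then allocate each stratum half
    and half at random.  Subsets are disjoint and exhaustive; stratum
    proportions are preserved within one subject."""
    rng = np.random.default_rng(seed)
    ids = cohort.subjects["subject_id"].to_numpy()
    counts = cohort.visits_per_subject().to_numpy()
    splits = []
    for _ in range(n_splits):
        a_parts, b_parts = [], []
        for stratum in np.unique(counts):
            members = np.where(counts == stratum)[0]
            if len(members) == 1:
                warnings.warn(f"stratum with {stratum} visits has a single "
                              "subject; allocated at random")
            perm = rng.permutation(members)
            half = len(perm) // 2
            extra = len(perm) % 2 and rng.random() < 0.5
            cut = half + (1 if extra else 0)
            a_parts.append(perm[:cut])
            b_parts.append(perm[cut:])
        idx_a = np.sort(np.concatenate(a_parts))
        idx_b = np.sort(np.concatenate(b_parts))
        splits.append((idx_a, idx_b))
    return SplitPlan(splits, ids, n_splits, seed)


# ---------------------------------------------------------------------------
# class stability (stage 1)
# ---------------------------------------------------------------------------

def class_stability(
    data: mlcmm.MLCMMData,
    spec: mlcmm.MLCMMSpec,
    plan: SplitPlan,
    full_fit: mlcmm.MLCMMFit | None = None,
    n_starts: int = 5,
    seed: int | None = None,
) -> StabilityReport:
    """Cross-subset class-prediction stability.

    For each split, the model is fitted on each subset; out-of-sample
    predictions from the model trained on the *other* subset are
    cross-tabulated with the in-sample assignments (kappa and ARI after
    Hungarian matching): two subset comparisons per split.  The combined
    in-sample subset assignments are also compared with the full-data model
    per split.  Failed subset fits are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    if full_fit is None:
        full_fit = mlcmm.fit(data, spec, n_starts=n_starts,
                             seed=int(rng.integers(2 ** 31)))
    id_to_pos = {s: i for i, s in enumerate(data.subject_ids)}
    rows = []
    for split_idx, (plan_a, plan_b) in enumerate(plan.splits):
        sides = {}
        ok = True
        for side, plan_idx in (("a", plan_a), ("b", plan_b)):
            pos = np.array([id_to_pos[s] for s in plan.subject_ids[plan_idx]
                            if s in id_to_pos])
            sub = data.subset(pos)
            try:
                f = mlcmm.fit(sub, spec, n_starts=n_starts,
                              seed=int(rng.integers(2 ** 31)))
            except RuntimeError as exc:
                warnings.warn(f"split {split_idx} subset {side} fit failed: {exc}")
                ok = False
                break
            sides[side] = (sub, f)
        if not ok:
            continue
        for side, other in (("a", "b"), ("b", "a")):
            sub, f_in = sides[side]
            _, f_out = sides[other]
            _, pred, _ = mlcmm.predict_class_newdata(f_out, sub)
            rows.append({
                "split": split_idx, "comparison": f"out_of_sample_{side}",
                "kappa": cs.cohens_kappa(f_in.labels, pred),
                "ari": cs.adjusted_rand(f_in.labels, pred),
            })
        # in-sample subset assignments vs the full-data model (one per
        # split); each subset model's labels are matched to the full-data
        # labelling separately before pooling, since the two subset fits
        # carry independent class numberings
        pooled_ids = np.concatenate([sides["a"][0].subject_ids,
                                     sides["b"][0].subject_ids])
        pooled_lab = np.concatenate([
            cs.match_labels(
                full_fit.labels[[id_to_pos[s]
                                 for s in sides[side][0].subject_ids]],
                sides[side][1].labels)
            for side in ("a", "b")])
        pos = np.array([id_to_pos[s] for s in pooled_ids])
        full_lab = full_fit.labels[pos]
        rows.append({
            "split": split_idx, "comparison": "subsets_vs_full",
            "kappa": cs.cohens_kappa(full_lab, pooled_lab),
            "ari": cs.adjusted_rand(full_lab, pooled_lab),
        })
    df = pd.DataFrame(rows)
    summary = _summarise(df, ("kappa", "ari"),
                         by=df["comparison"].str.startswith("out_of_sample"))
    return StabilityReport(df, summary)


def _summarise(df: pd.DataFrame, stats, by=None) -> dict:
    out = {}
    groups = {"all": df}
    if by is not None:
        groups["subset_comparisons"] = df[by]
        groups["full_data_comparisons"] = df[~by]
    for gname, gdf in groups.items():
        for stat in stats:
            vals = gdf[stat].dropna()
            if not len(vals):
                continue
            out[f"{gname}_{stat}_mean"] = float(vals.mean())
            out[f"{gname}_{stat}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# cluster stability (stage 2)
# ---------------------------------------------------------------------------

def cluster_stability(
    profiles: pr.ProfileDataset,
    plan: SplitPlan,
    priors: pr.DPMMPriors | None = None,
    n_chains: int = 6,
    n_iter: int = 10000,
    burn_in: int = 2000,
    thin: int = 10,
    k_range=range(2, 16),
    seed: int | None = None,
    full_result: dict | None = None,
) -> StabilityReport:
    """Cluster-structure stability under repeated sub-setting.

    Per subset: consensus PSM and representative clustering, compared with
    the full-data consensus restricted to the subset (lower-triangle
    Pearson r, ARI).  Held-out predictions from the model trained on the
    other subset give predicted dissimilarities (compared with the full
    consensus off-diagonal blocks) and predicted clusterings (nearest
    representative training cluster by mean predicted dissimilarity,
    compared with the held-out subset's own representative clustering).
    """
    priors = priors or pr.DPMMPriors()
    rng = np.random.default_rng(seed)
    opts = dict(n_iter=n_iter, burn_in=burn_in, thin=thin)

    if full_result is None:
        chains = pr.run_chains(profiles, priors, n_chains=n_chains,
                               seed=int(rng.integers(2 ** 31)), **opts)
        full_psm = cs.consensus([cs.compute_psm(c.alloc, c.subject_ids)
                                 for c in chains])
        full_rep = cs.representative_clustering(full_psm, k_range)
    else:
        full_psm, full_rep = full_result["psm"], full_result["rep"]

    rows = []
    for split_idx, (idx_a, idx_b) in enumerate(plan.splits):
        fitted = {}
        for side, idx in (("a", idx_a), ("b", idx_b)):
            sub = profiles.subset(idx)
            sub_chains = pr.run_chains(sub, priors, n_chains=n_chains,
                                       seed=int(rng.integers(2 ** 31)), **opts)
            sub_psm = cs.consensus([cs.compute_psm(c.alloc, c.subject_ids)
                                    for c in sub_chains])
            sub_rep = cs.representative_clustering(sub_psm, k_range)
            fitted[side] = (idx, sub, sub_chains, sub_psm, sub_rep)

            full_block = full_psm.restrict(idx)
            rows.append({
                "split": split_idx, "subset": side,
                "comparison": "subset_vs_full",
                "pearson_r": cs.lower_triangle_correlation(sub_psm, full_block),
                "ari": cs.adjusted_rand(sub_rep.labels,
                                        full_rep.labels[idx]),
            })
        for side, other in (("a", "b"), ("b", "a")):
            idx_tr, _, tr_chains, _, tr_rep = fitted[other]
            idx_ho, sub_ho, _, _, ho_rep = fitted[side]
            pred_new, pred_cross = _pooled_prediction(
                tr_chains, sub_ho.without_outcome(),
                seed=int(rng.integers(2 ** 31)))
            # held-out predicted dissimilarity vs full-data off-diagonal block
            cross_block = 1.0 - full_psm.S[np.ix_(idx_ho, idx_tr)]
            r = np.corrcoef(pred_cross.ravel(), cross_block.ravel())[0, 1] \
                if cross_block.size > 1 else np.nan
            # predicted clustering: nearest training representative cluster
            # by mean predicted dissimilarity (ties toward the larger cluster)
            pred_labels = _nearest_cluster(pred_cross, tr_rep.labels)
            rows.append({
                "split": split_idx, "subset": side,
                "comparison": "held_out_prediction",
                "pearson_r": float(r),
                "ari": cs.adjusted_rand(ho_rep.labels, pred_labels),
            })
    df = pd.DataFrame(rows)
    summary = _summarise(df, ("pearson_r", "ari"),
                         by=df["comparison"] == "subset_vs_full")
    summary["full_n_clusters"] = int(full_rep.chosen_k)
    return StabilityReport(df, summary)


def _pooled_prediction(chains, new_profiles, seed=None):
    """Predicted dissimilarities pooled over a training subset's chains."""
    rng = np.random.default_rng(seed)
    d_new, d_cross, n = 0.0, 0.0, 0
    for chain in chains:
        alloc = pr.predict_allocation(chain, new_profiles,
                                      seed=int(rng.integers(2 ** 31)))
        dn, dc = pr.predicted_dissimilarity(chain, alloc)
        d_new = d_new + dn
        d_cross = d_cross + dc
        n += 1
    return d_new / n, d_cross / n


def _nearest_cluster(pred_cross: np.ndarray, train_labels: np.ndarray
                     ) -> np.ndarray:
    """Assign each held-out subject to the training cluster with smallest
    mean predicted dissimilarity; ties go to the larger cluster."""
    clusters = np.unique(train_labels)
    sizes = np.array([(train_labels == c).sum() for c in clusters])
    mean_d = np.column_stack([
        pred_cross[:, train_labels == c].mean(axis=1) for c in clusters])
    # smallest mean dissimilarity wins; exact ties go to the larger cluster
    # via an epsilon size bonus far below any real dissimilarity difference
    adjusted = mean_d - 1e-12 * sizes[None, :]
    return clusters[np.argmin(adjusted, axis=1)]
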