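#!/usr/bin/env python
"""Summarise the MCMC chains into consensus biomarker endotypes.

Computes per-chain posterior similarity matrices, their pairwise agreement
(lower-triangle Pearson correlation, adjusted Rand index of representative
clusterings), the consensus representative clustering, cluster-averaged
parameter posteriors with 90% credible intervals, the cluster-by-class
composition, and the agreement between the outcome-guided clustering and
the biomarker-only reference clustering.  Results land in results/clusters/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from trajclust import cluster_summary as cs
from trajclust import profile_regression as pr


def load_chains(out_dir: Path, tag: str):
    chains = []
    for path in sorted(out_dir.glob(f"{tag}_chain*.npz")):
        z = np.load(path, allow_pickle=False)
        theta_out = z["theta_out"] if z["theta_out"].size else None
        n_kept = z["alloc"].shape[0]
        chains.append(pr.ChainOutput(
            z["alloc"], z["log_w"], theta_out, z["theta_bin"], z["mu"],
            z["sigma"], z["alpha"], z["subject_ids"],
            pr.MCMCOptions(n_iter=n_kept, burn_in=0, thin=1)))
    return chains


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--profreg-dir", type=Path, default=Path("results/profreg"))
    ap.add_argument("--mlcmm-dir", type=Path, default=Path("results/mlcmm"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/clusters"))
    ap.add_argument("--max-k", type=int, default=12)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    chains = load_chains(args.profreg_dir, "guided")
    agreement = cs.chain_agreement(chains, range(2, args.max_k + 1))
    agreement["pairs"].to_csv(args.out_dir / "chain_agreement.csv",
                              index=False)
    print(f"chain agreement: mean pairwise Pearson r = "
          f"{agreement['mean_pearson']:.3f} (sd {agreement['sd_pearson']:.3f}), "
          f"mean pairwise ARI = {agreement['mean_ari']:.3f} "
          f"(sd {agreement['sd_ari']:.3f})")

    consensus = cs.consensus(agreement["chain_psms"])
    rep = cs.representative_clustering(consensus, range(2, args.max_k + 1))
    print(f"consensus representative clustering: {rep.chosen_k} clusters, "
          f"sizes {np.bincount(rep.labels).tolist()}")
    chain_vs_consensus = [
        cs.adjusted_rand(rep.labels, r.labels)
        for r in agreement["chain_clusterings"]]
    print("ARI of each chain's clustering vs the consensus:",
          np.round(chain_vs_consensus, 3).tolist())
    pd.DataFrame({"subject_id": rep.subject_ids, "cluster": rep.labels}) \
        .to_csv(args.out_dir / "representative_clustering.csv", index=False)

    posteriors = cs.cluster_param_posteriors(chains, rep)
    posteriors.to_csv(args.out_dir / "cluster_parameter_posteriors.csv",
                      index=False)

    labels_df = pd.read_csv(args.mlcmm_dir / "posterior.csv")
    merged = labels_df.merge(
        pd.DataFrame({"subject_id": rep.subject_ids, "cluster": rep.labels}),
        on="subject_id")
    composition = pd.crosstab(merged["cluster"], merged["label"],
                              normalize="index").round(3)
    composition.to_csv(args.out_dir / "cluster_class_composition.csv")
    print("empirical class composition per cluster:")
    print(composition.to_string())

    ref_chains = load_chains(args.profreg_dir, "reference")
    ref_psm = cs.consensus([cs.compute_psm(c.alloc, c.subject_ids)
                            for c in ref_chains])
    ref_rep = cs.representative_clustering(ref_psm, range(2, args.max_k + 1))
    ari_ref = cs.adjusted_rand(rep.labels, ref_rep.labels)
    print(f"biomarker-only reference clustering: {ref_rep.chosen_k} clusters; "
          f"ARI vs outcome-guided clustering = {ari_ref:.2f}")
    (args.out_dir / "summary.json").write_text(json.dumps({
        "consensus_k": int(rep.chosen_k),
        "cluster_sizes": np.bincount(rep.labels).tolist(),
        "mean_pairwise_pearson": agreement["mean_pearson"],
        "mean_pairwise_ari": agreement["mean_ari"],
        "chain_vs_consensus_ari": chain_vs_consensus,
        "reference_k": int(ref_rep.chosen_k),
        "ari_guided_vs_reference": ari_ref}, indent=2))


if __name__ == "__main__":
    main()
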