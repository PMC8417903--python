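#!/usr/bin/env python
"""Outcome-guided biomarker clustering of the fitted trajectory classes.

Builds the profile-regression dataset (hard class assignments from stage 1
as the categorical outcome; five binary pathology flags; four standardised
volumetric covariates), runs independent MCMC chains of the
Dirichlet-process mixture, and stores the kept allocations plus a
biomarker-only reference run under results/profreg/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from trajclust import data_prep, profile_regression as pr, synthetic
from trajclust.data_prep import CohortTable


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--mlcmm-dir", type=Path, default=Path("results/mlcmm"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/profreg"))
    ap.add_argument("--chains", type=int, default=6)
    ap.add_argument("--iters", type=int, default=4000)
    ap.add_argument("--burnin", type=int, default=1000)
    ap.add_argument("--thin", type=int, default=10)
    ap.add_argument("--seed", type=int, default=3)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = CohortTable.from_csv(args.data_dir / "subjects.csv",
                                  args.data_dir / "visits.csv")
    eligible, _ = data_prep.filter_eligible(cohort, require_apoe=True)
    posterior = pd.read_csv(args.mlcmm_dir / "posterior.csv")
    labels = posterior.set_index("subject_id")["label"]
    keep = eligible.subjects["subject_id"].isin(labels.index)
    eligible = CohortTable(
        eligible.subjects[keep].reset_index(drop=True),
        eligible.visits[eligible.visits.subject_id.isin(
            labels.index)].reset_index(drop=True))
    y = labels.loc[eligible.subjects["subject_id"]].to_numpy()
    profiles = synthetic.build_profile_dataset(eligible, y, int(y.max()) + 1)
    print(f"profile dataset: {profiles.n_subjects} subjects, "
          f"{np.isnan(profiles.w_bin).sum()} missing binary and "
          f"{np.isnan(profiles.w_cont).sum()} missing continuous entries")

    priors = pr.DPMMPriors()
    for tag, dataset in (("guided", profiles),
                         ("reference", profiles.without_outcome())):
        chains = pr.run_chains(dataset, priors, n_chains=args.chains,
                               seed=args.seed, n_iter=args.iters,
                               burn_in=args.burnin, thin=args.thin)
        for c_idx, chain in enumerate(chains):
            np.savez_compressed(
                args.out_dir / f"{tag}_chain{c_idx}.npz",
                alloc=chain.alloc, log_w=chain.log_w,
                theta_out=(chain.theta_out if chain.theta_out is not None
                           else np.array([])),
                theta_bin=chain.theta_bin, mu=chain.mu, sigma=chain.sigma,
                alpha=chain.alpha,
                subject_ids=np.asarray(chain.subject_ids, dtype=str))
        occ = np.concatenate([[len(np.unique(a)) for a in c.alloc]
                              for c in chains])
        print(f"{tag}: {args.chains} chains x {args.iters} iterations; "
              f"posterior occupied components "
              f"median {int(np.median(occ))} (IQR {np.percentile(occ, 25):.0f}"
              f"-{np.percentile(occ, 75):.0f}); "
              f"mean alpha {np.mean([c.alpha.mean() for c in chains]):.2f}")
    print(f"chain output written to {args.out_dir}")


if __name__ == "__main__":
    main()
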