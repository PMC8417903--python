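# trajclust

Two-stage disease modelling for longitudinal pre-dementia cohorts:

1. **Latent clinical phenotypes** — a multivariate latent-class linear
   mixed effects model (MLCMM) identifies G latent classes of cognitive
   trajectories from repeated CDRSB and MMSE measurements. A shared latent
   process Λ_i(t) drives both outcomes through outcome-specific linear
   links,

       Ỹ_ijk = (Y_ijk − η₁k)/η₂k = Λ_i(t_ijk) + ε_ijk,
       Λ_i(t) | c_i = g  =  x_i'β + γ_g0 + γ_g1·t + u_ig,

   with class-specific random intercepts u_ig ~ N(0, ω_g·B), a
   multinomial-logistic membership model P(c_i = g) = softmax(ξ₀)_g, and
   class number chosen by BIC and relative entropy.

2. **Neuropathological endotypes** — Bayesian profile regression links the
   hard class assignments ĉ_i (as a categorical outcome) to CSF and
   neuroimaging biomarker profiles through a Dirichlet-process mixture:
   five binary pathology flags (CSF pTau/Aβ positivity, MTA, two Fazekas
   scales, combined ARWMC) with Bernoulli likelihoods and four standardised
   continuous covariates (hippocampal and ventricular volumes and their
   annualised rates of change) with a multivariate-Gaussian likelihood.
   Blocked-Gibbs MCMC chains are summarised through the posterior
   similarity matrix; PAM on 1 − S with silhouette selection gives a
   representative clustering, and multi-chain consensus the final
   endotypes.

The package also provides the shared variable derivations (outcome
transformations, biomarker dichotomisation, eligibility filtering, cohort
summaries), a split-half stability validation framework (Cohen's kappa,
adjusted Rand index, PSM correlations, held-out prediction), and a
synthetic cohort generator whose defaults reproduce the published 4-class
/ 7-cluster structure so every stage can be tested against ground truth
without access to the restricted cohort data.

Intended users: biostatisticians and quantitative researchers stratifying
longitudinal cohort data (cognitive ageing, AD prevention trials) who need
a transparent, testable implementation of the latent-class → profile-
regression pipeline.

## Worked example

```python
import numpy as np
from trajclust import synthetic, data_prep, mlcmm

cfg = synthetic.scenario("crisp_classes", n_subjects=500)
cohort, profiles, truth = synthetic.generate_cohort(cfg, seed=1)
eligible, log = data_prep.filter_eligible(cohort, require_apoe=True)
data = mlcmm.MLCMMData.from_cohort(eligible)
fit = mlcmm.fit(data, mlcmm.MLCMMSpec(n_classes=2), n_starts=3, seed=2)
print(f"loglik {fit.loglik:.2f}  BIC {fit.bic:.2f}  entropy {fit.entropy:.3f}")
print("class shares:", np.round(np.bincount(fit.labels) / len(fit.labels), 3))
```

prints

```
loglik -7004.50  BIC 14113.56  entropy 0.997
class shares: [0.61 0.39]
```

i.e. the fitted 2-class model separates the cohort essentially crisply
(relative entropy 0.997; 1 would be a perfectly certain classification)
into the two generating trajectory groups — here 61% / 39%, recovering
the generating 60/40 membership split.

The full analysis sequence on a simulated cohort lives under `analysis/`
(each script prints what it found and writes tables under `results/`):

```bash
python analysis/01_simulate_cohort.py        # cohort + truth CSVs
python analysis/02_fit_trajectory_classes.py # G=1..4 fits, BIC table, trajectories
python analysis/03_profile_regression.py     # DPMM chains (guided + reference)
python analysis/04_consensus_clusters.py     # consensus endotypes, credible intervals
python analysis/05_stability_validation.py   # split-half stability report
```

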