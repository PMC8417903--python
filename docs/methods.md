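# Methods

`trajclust` implements a two-stage stratification of a longitudinal
pre-dementia cohort: latent-class modelling of cognitive trajectories,
followed by outcome-guided Bayesian clustering of biomarker profiles. This
note records the models, the numerical choices, and what the synthetic test
bed does and does not establish.

## Variable derivations

CDRSB (Clinical Dementia Rating Sum of Boxes, 0–18 in 0.5 steps) has strong
floor effects in a largely unimpaired cohort; it is mapped to
`tCDRSB = -log((c + 0.1) / (18 - c + 0.1))`, a strictly decreasing bijection
of [0, 18] onto [-5.1985, 5.1985] (higher = better functioning). MMSE
(0–30) is mapped to a 0–100 "nMMSE" scale through a 31-entry monotone
lookup that corrects the curvilinearity of the raw score. The published
normalisation table is not reproduced here; the shipped table
(`resources/mmse_norm_synthetic.json`, labelled synthetic) preserves its
qualitative shape — score differences near the ceiling are expanded — and a
linear rescaling (`mmse/30*100`) is available as a fallback. Any analysis
of real data should substitute the published table; all grid resolutions
below refer to the shipped one.

Radiological reads are dichotomised at the conventional cut-offs: medial
temporal atrophy (MTA, left/right average) is positive at >= 1, with 0.5
kept as an explicit "inconclusive" level that collapses to negative in the
binary covariate; Fazekas deep >= 2; Fazekas periventricular >= 1; the
combined ARWMC count is the number of the five regional scores >= 1, with
>= 3 regions flagged. CSF pTau/Abeta42 > 0.024 defines AD positivity.
Annualised volume change is (last - baseline) / years between scans.
Continuous covariates are standardised with the sample (n-1) SD over the
analysis set after eligibility filtering; percentages in summary tables use
non-missing denominators and one-decimal rounding (two decimals for model
criteria).

Education enters as a 3-level attainment variable (level 1 reference,
dummies for levels 2 and 3); the mapping from country-specific years of
education to levels is the caller's responsibility — no country rules are
hard-coded.

## Stage 1: multivariate latent-class linear mixed model

With K = 2 outcomes linked linearly to a shared latent process,
`Ytilde_ijk = (Y_ijk - eta_1k)/eta_2k = Lambda_i(t_ijk) + eps_ijk` and
`Lambda_i(t) | c_i = g = x_i' beta + gamma_g0 + gamma_g1 t + u_ig`, with
`u_ig ~ N(0, omega_g B)` a class-specific random intercept (B = 1) and
`eps_ijk ~ N(0, sigma_k^2)` independent errors on the latent scale. Class
membership is multinomial-logistic without covariates:
`P(c_i = g) = softmax(xi_0)_g`. Identifiability: class 0's fixed intercept
is 0 (absorbed by eta_1), the last class's random-intercept variance is 1
(pinning the latent scale), and the last class's membership logit is 0. All
three reference indices are configurable. For G classes, p covariates and
K = 2 outcomes the free-parameter count is 3(G-1) + G + p + 3K — 25 for
G = 4, p = 6, matching the 4-class model's criterion arithmetic.

Because only a random intercept enters, the class-conditional marginal
covariance is compound-symmetric, `omega_g 11' + diag(sigma_k^2)`, and the
marginal likelihood is available in closed form via Sherman–Morrison and
the matrix determinant lemma; the Jacobian `-sum log eta_2k` puts it on the
observed-outcome scale. Missing outcomes at a visit contribute nothing
(MAR); a subject needs only one observed outcome.

**Estimation.** Direct multi-start quasi-Newton (L-BFGS-B) maximisation of
the observed-data mixture log-likelihood with an analytic gradient (mixture
responsibilities combined with the closed-form derivatives of the
compound-symmetry Gaussian), in an unconstrained parameterisation (log
transforms for eta_2, sigma, omega; xi_0 in the same vector). An EM wrapper
was considered and rejected: with no covariates in the membership submodel
the EM pi-update buys nothing over joint quasi-Newton, and the vectorised
likelihood evaluation is cheap. The default 30 starts comprise one
perturbed single-class fit and 29 random perturbations of the moment start;
the optimiser runs at relative tolerance 1e-11 and is finished by restarted
"polish" passes at near-zero `ftol`, which force L-BFGS through the flat
tail of the likelihood (termination at looser tolerances was observed to
leave ~1e-3 log-likelihood units on the table, enough to distort the link
scales). Determinism: every draw flows from the user seed.

Standard errors come from the numerically differentiated observed
information (central differences of the analytic gradient) with the delta
method mapping log-scale parameters back to natural scale; trajectory bands
are delta-method 95% intervals on the latent scale. BIC is
`-2 loglik + p log N`; relative entropy is `1 - H/(N log G)` with H the
Shannon entropy of the posterior membership matrix (1 = crisp, defined as 1
at G = 1; the formula is stated here because software conventions differ).
Hard assignment takes the row-wise argmax, ties broken to the lowest class
index with a warning.

## Stage 2: Bayesian profile regression

A Dirichlet-process mixture couples the stage-1 hard class assignment
(categorical outcome) to five Bernoulli pathology flags and a 4-dimensional
Gaussian block (HV, VV and their annualised rates, standardised), all
conditionally independent given cluster. The stick-breaking prior
(`V_h ~ Beta(1, alpha)`, `alpha ~ Gamma(2, 1)`) is truncated at H = 50
components and sampled by a blocked Gibbs sampler; a warning is raised if
the boundary component is ever occupied. Conjugate priors: Beta(1, 1) per
binary covariate, Dirichlet(1) on the outcome simplex, and
normal-inverse-Wishart (mu0 = 0, kappa0 = 0.01, nu0 = dim + 2, Psi0 = I)
for the Gaussian block — sensible defaults for standardised covariates,
documented as substitutes for the unpublished defaults of the original
software, and all configurable.

The concentration alpha is updated by the Escobar–West auxiliary-variable
scheme with the truncated sampler's occupied-component count playing the
role of the cluster count. (The exact conjugate Gamma update for the
truncated sticks was tried first and discarded: with H = 50 mostly-empty
components its posterior is dominated by prior stick draws, so alpha never
adapts to the data and spurious cluster splits inflate.)

Missing covariates are imputed within the MCMC from the allocated
component's conditional distribution; the allocation step simply skips the
factors of entries not yet imputed (first sweep). Sweep order: allocations
(Gumbel-max in log space), sticks, imputation, conjugate component-
parameter updates, alpha. Held-out subjects are allocated per kept
iteration from the covariate factors only — their class is the quantity
being predicted — giving predicted co-clustering dissimilarities.

Desk-scale defaults are 6 chains of 20,000 iterations (burn-in 5,000, thin
10); the published analysis scale (350,000/100,000) is reachable through
the same options.

## Consensus summarisation

The posterior similarity matrix (PSM) S holds pairwise co-clustering
proportions over kept iterations; chains are aggregated by element-wise
averaging (consensus). Partitioning around medoids on 1 - S gives the
representative clustering, with k in {2, ..., 15} (configurable) selected
by average silhouette width, ties to smaller k; an all-ones PSM degenerates
to a single cluster with a warning. PAM is deterministic: greedy BUILD then
steepest-descent SWAP, with exhaustive enumeration replacing the heuristic
whenever the medoid-set space is small (C(N, k) <= 3000), so tiny instances
are provably optimal. Cluster-averaged component-parameter posteriors
(average over a representative cluster's members of their allocated
component's parameter, per kept iteration) are summarised by the mean and a
90% credible interval.

Agreement statistics: Hubert–Arabie adjusted Rand index; Cohen's kappa
computed after Hungarian matching of cluster labels (maximising the
confusion-table trace), since kappa needs a label correspondence; Pearson
correlation of strictly-lower-triangle matrix entries. Degenerate cases
(constant labellings, zero-variance triangles) return NaN with a warning
rather than an arbitrary number.

## Stability validation

Ten (configurable) stratified split-halves: subjects are stratified by
visit count and allocated to two subsets with equal probability within each
stratum (within one subject of balance). Class stability refits the MLCMM
per subset, cross-predicts the held-out subset, and cross-tabulates
out-of-sample predictions against in-sample assignments (kappa, ARI after
matching) — two subset comparisons per split — plus one per-split
comparison of the combined in-sample assignments against the full-data
model. Cluster stability compares each subset's consensus PSM and
representative clustering with the full-data analysis restricted to the
subset, and compares held-out predicted dissimilarities and predicted
cluster memberships (nearest training cluster by mean predicted
dissimilarity, ties to the larger cluster; "mean" chosen because the
medoid-based alternative is not determined by the framework's description)
with the corresponding full-data blocks and subset analyses. Subset
analyses use reduced MCMC settings by default.

## Synthetic cohorts

The generator draws the full two-stage structure in the generative
direction: class from softmax(xi_0); cluster from the class-conditional
table obtained by Bayes-inverting the cluster-conditional class
probabilities with the configured cluster weights (that orientation matches
how coupled cluster profiles are naturally reported); random intercept;
latent process; outcomes on the transformed scales, back-transformed onto
the instrument grids (CDRSB rounded to its 0.5 grid and clamped to [0, 18];
MMSE inverted through the lookup to integers in [0, 30]). Visits follow
(0, 0.5, 1, 2, 3) years with monotone attrition (retention defaults 0.857,
0.758, 0.333, 0.225 — the observed per-visit continuation of the motivating
cohort); MMSE is absent at the 6-months visit by design. Risk factors use
the motivating cohort's marginals (age ~ N(65.4, 7.4^2) truncated at 50;
56.4% female; education 37.3/25.0/37.7%; family history 65.5%; APOE e4
37.5% with 2% missingness). Binary biomarkers are drawn from cluster
positivity profiles and realised as raw scores consistent with the
dichotomisation cut-offs; continuous biomarkers are Gaussian on the
standardised scale with cluster means, unit variances, and 0.3 correlation
between each volume and its own rate (the within-cluster covariances are
not published; this is a placeholder), then mapped to raw mm^3 scales.

The `epad_like` preset uses the published 4-class and 7-cluster estimates
at n = 1,543. The crisp presets are recovery test beds, not cohort
emulations: `crisp_classes` has two classes 6 latent units apart (>= 4
residual SDs at sigma = (1.0, 1.2)) placed mid-scale on both instruments —
placement matters because near the healthy ceiling most CDRSB values clamp
to 0 and the MMSE lookup is coarse, so the continuous model is misspecified
for grid-rounded data and ML estimates of the variance components absorb
the discretisation; mid-scale, the grids are fine relative to the noise and
generating parameters are recovered within standard errors.
`crisp_clusters` has three equally weighted clusters separated by >= 5.7
SDs in the Gaussian block with near-deterministic class coupling.
`null_structure` (one class, one cluster) and `small_test` (tiny crisp
cohort, no attrition) complete the presets.

**What passing tests show.** Recovery on crisp synthetic data establishes
the estimation and summarisation machinery, not performance on real
cohorts: real data have classes of very unequal size and overlap, outcome
floors (the structureless majority class sits at the CDRSB floor),
informative dropout beyond MAR, site effects, and biomarker distributions
that are neither Bernoulli-independent nor Gaussian within cluster. The
generator reproduces none of the recruitment-enrichment mechanism beyond
marginal rates.

## Problem sizes and numerical conventions

The test suite runs the recovery suites at the scales stated with the
acceptance checks: 20 replicates of n = 500 for class-parameter recovery;
n = 300 with 6 chains x 5,000 iterations for cluster recovery; two
split-halves at reduced MCMC settings for stability. The analysis scripts
default to n = 600 cohorts with 4,000-iteration chains; all sizes are
flags. Convergence: L-BFGS relative tolerance 1e-11 with near-zero-`ftol`
polish, gradient norm 1e-7 (1e-8 in polish), max 500 iterations per start.
Gauss–Hermite cross-checks use 150 nodes with adaptive centring. PSMs are
accumulated in int32; allocation sampling uses the Gumbel-max trick in log
space throughout.

## Known limitations

Single random intercept only (no random slopes), linear links only, no
covariates in the membership submodel, no variable selection in the profile
regression, no joint survival modelling, no external-cohort validation.
Standard errors ignore multi-start selection and, for the entropy, the
classification uncertainty. The blocked Gibbs sampler has no split-merge
moves, so single chains can transiently over-split tight clusters; the
silhouette criterion occasionally ratifies such splits at k one above the
truth even when the partition is otherwise correct (ARI stays high), which
is why multi-chain consensus is the default reporting route.
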