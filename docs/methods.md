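# Methods

This note records the models, the numerical choices, and what the synthetic
cohort does and does not emulate.

## Cohort model and preparation

A cohort is a subject × variable table under a typed schema: binary disease
indicators, categorical/continuous covariates, three outcomes
(hospitalisation yes/no; readmission count; length-of-stay days, the latter
two defined only for hospitalised subjects), and a complex-survey design
(stratum, PSU, weight).  "Don't know / no answer" responses are treated as
missing cells; a row missing any analysis variable is a non-complete case.

**Exclusion accounting.** `exclusion_report` counts and removes rows
missing any declared analysis variable and reports baseline n, flagged n,
the percentage (one decimal) and the final n.  Rows are conserved:
kept + removed = baseline.

**IPW.** The probability of being a complete case is modelled by a
maximum-likelihood logit on fully observed covariates; complete rows get
multiplier 1/p̂, incomplete rows none.  The final analysis weight is the
survey weight × IPW multiplier (multiplicative composition; the
alternative, design weights alone, is available via `weight_mode="survey"`
in the pipeline).  A constant complete-case indicator or perfect separation
is refused rather than silently producing degenerate weights.

**Asset index.** The score is the first principal component of the
standardised 12-variable asset block (correlation-scale PCA), cut into
weighted quintiles (left-closed/right-open, last interval closed).  A
principal axis has no intrinsic sign, so the score is canonicalised from
its own distribution: the orientation with non-negative weighted skewness
is kept, with correlation against the standardised column mean as a
tie-break.  Asset scores are strongly right-skewed in practice (few
households hold many assets; published quintile boundaries are much wider
at the top), which makes this orientation coincide with "higher score =
more assets" while staying invariant under a global sign flip of the
inputs.  Zero-variance columns are dropped with a warning.

**Design-based prevalence.** Horvitz–Thompson ratio estimate; variance by
stratified between-PSU Taylor linearisation
(Σ_h n_h/(n_h−1) Σ_j (z_hj − z̄_h)² with z the weighted linearised scores);
95% CI Wald on the logit scale, back-transformed; degenerate interval at
prevalence 0 or 1.  Strata with a single PSU are a hard error by default —
silent variance misestimation is worse than refusal — with an explicit
`single_psu="collapse"` option that pools all such strata.

## Association models

**Prevalence ratios.** Log-link Poisson regression of the binary outcome
(modified Poisson), fitted by IRLS (statsmodels; deviance tolerance 1e-10,
100 iterations), with a CR0 cluster sandwich computed in-package:
bread (XᵀWX)⁻¹ from the IRLS information, meat from per-PSU sums of
weighted score contributions wᵢ(yᵢ−μᵢ)xᵢ, no small-sample correction.  With
one observation per cluster and unit weights this is exactly HC0.  CIs are
Wald on the log scale (z = 1.959964), exponentiated.  Covariate levels with
zero outcome events are reported with unbounded CIs and a warning; a
constant-zero outcome is refused.

**Linear models.** Weighted least squares with the same PSU-clustered
sandwich, used for readmission and length of stay on the hospitalised
subset — readmission is undefined off it.  Rank-deficient designs raise an
error naming the aliased terms (QR with pivoting).

**Goodman–Kruskal γ.** γ = (C−D)/(C+D) over concordant/discordant pairs of
an ordered r×c table, accumulated with cumulative-sum tables; the classical
asymptotic SE 4·√(Σ nᵢⱼ(D·Aᵢⱼ − C·Bᵢⱼ)²)/(C+D)².  Tests verify it against a
brute-force O(cells²) pair enumeration.

## Network estimation

Estimation is nodewise pseudo-likelihood, the de-facto standard for
regularised Ising/mixed graphical models: node j is regressed on all other
nodes with an ℓ1-penalised GLM whose family follows the node type (binary →
logistic, count → Poisson log-link offered raw, continuous → Gaussian
standardised to unit variance).

**Coordinate descent.** Predictors are standardised internally; for each λ
on a descending geometric grid (default 100 values down to 0.01·λ_max,
warm-started) coefficients minimise (1/n)·NLL + λ‖β‖₁ with an unpenalised
intercept, by IRLS around cyclic coordinate descent on the weighted working
response (numba kernels).  Convergence: largest absolute coefficient update
< 1e-7; IRLS weights floored at 1e-6 and linear predictors clipped at ±30
to keep rare-event nodes finite.  KKT conditions at the solution are
exposed (`kkt_violation`) and tested to 1e-5.

**EBIC.** EBIC(λ) = −2ℓ(λ) + df·log n + 2γ·df·log p_cand with γ = 0.25,
df = number of nonzero penalised coefficients, p_cand = p−1 predictors
offered to the node, and ℓ the log-likelihood of the penalised estimate
(the convention of the nodewise-Ising literature).  Ties select the sparser
(larger-λ) model.

**Symmetrisation.** AND rule by default (edge kept only if both directed
coefficients are nonzero); OR available.  Ising edge weight = mean of the
two directed logistic coefficients (its sign is the coupling sign); MGM
edge strength = mean absolute value with a sign attribute, marked
undetermined (0) when the directions disagree.  Sampling weights are *not*
used in network estimation — fits are unweighted on the complete-case
block, and the hospitalised subset for the readmission and length-of-stay
networks.

## Network analysis

**Walktrap.** t = 4 step transition probabilities P = D⁻¹W on absolute
edge weights; community distance r²(C₁,C₂) = Σ_k (P^t_{C₁k} − P^t_{C₂k})²/d_k;
greedy merges of adjacent communities minimising Δσ =
(|C₁||C₂|/(|C₁|+|C₂|))·r²/n, recorded as a dendrogram and cut at maximum
Newman modularity.  Disconnected components are processed independently and
never merged.  The partition is invariant to uniform rescaling of weights;
on planted two-block graphs it agrees with the igraph reference
implementation in 100/100 seeded runs.  Negative edge weights enter
community detection and the flow layout as absolute values (a random walk
needs non-negative weights — the standard psychometric-network practice);
signs are preserved in all exports.

**Predictability.** Each node is refit without penalty on its selected
neighbours; binary nodes report in-sample correct classification at the 0.5
threshold against the larger marginal class share as baseline, count and
continuous nodes report in-sample variance explained (clipped at 0 for the
non-Gaussian case) against baseline 0.  Isolated nodes score exactly their
baseline and are flagged.

**Bootstrap & stability.** Edge accuracy: n-out-of-n resampling with
replacement, per-edge 2.5/50/97.5% quantiles and inclusion proportions;
replicates failing to fit are dropped and counted, >10% failures aborts.
Stability: case-dropping subsamples at fractions 0.1…0.7, correlating each
subsample's edge vector with the full-sample vector; the CS coefficient is
the largest fraction at which the correlation stays ≥ 0.7 in ≥ 95% of
replicates, scanning upward so the qualifying set is contiguous; an
undefined correlation (constant edge vector) counts as failure, so
pure-noise data yields CS = 0.

**Flow layout.** Unweighted BFS distance to the target node over nonzero
edges defines the layer (target alone in layer 0); unreachable nodes share
a sentinel final layer; within-layer order is one barycenter pass over the
previous layer with label-order tie-break.

## Synthetic cohort

The generator emulates the structure of a survey-baseline ageing cohort:
9,412 subjects by default, 10 strata × 7 PSUs (≈ 70 sampling units),
covariate marginals (53.7% female; age bands 48.3/38.3/13.4%; 85% urban;
63.7% with partner), 19 binary chronic conditions, hospitalisation
calibrated to 10% prevalence, and ~6.4% of rows flagged by a
missing-at-random mechanism.

- **Diseases** come from the pairwise binary model; couplings are sparse
  (density 0.15) and positive (0.3–0.9: chronic conditions co-occur),
  thresholds τ ~ U(−4.2, −1.0) give prevalences from ~2% to ~35%, and age
  shifts thresholds additively (+0.3/+0.6 for the older bands), producing
  the age gradient in multimorbidity without extra pairwise structure.
  Exact enumeration sampling is used for p ≤ 15; beyond that a single-chain
  Gibbs sampler (burn-in 300 sweeps, thinning 10) with rows shuffled
  afterwards so residual chain autocorrelation never aligns with the
  design.
- **Hospitalisation** is Bernoulli with a log-link linear predictor in the
  covariates and multimorbidity category (effects on the prevalence-ratio
  scale: male 1.41, no partner 1.21, two conditions 1.58, three or more
  2.39); the intercept has the closed form log(target) − log(mean e^η), and
  calibration fails loudly if any event probability reaches 1.
- **Readmission** is 1 + Poisson with a log-rate linear predictor
  (admitted subjects have at least one admission by definition), intercept
  calibrated so the mean is ≈ 1.55.  **Length of stay** is lognormal with
  log-scale SD 1.153, calibrated to mean ≈ 6 days (giving SD ≈ 10, i.e.
  strongly right-skewed and overdispersed), with log-scale effects for sex
  (+0.45) and rural residence (−0.55).
- **Design.** Subjects land uniformly in strata and PSUs; each PSU carries
  a weight factor ~ U(1, 5) (inverse inclusion probability, independent of
  outcomes); per-stratum weight sums are recorded as the notional stratum
  population.  These weights are a stand-in for a real survey's weight
  construction, not a reconstruction of one.
- **Missingness** flags rows with probability logistic(c + η) in observed
  covariates (default: older age raises, male lowers), the intercept solved
  by root-finding so the expected flagged share equals the target; each
  flagged row has one randomly chosen disease cell blanked, keeping
  covariates complete so they remain valid IPW predictors.

What passing tests on these cohorts show — and do not.  The generator's
conditional models are exactly the ones the estimators assume (log-link
Bernoulli, pairwise Ising, MAR missingness), so recovery tests validate the
estimation machinery, not robustness to model misspecification,
questionnaire measurement error, interviewer effects or informative
sampling, none of which are emulated.  Rare conditions (2–4% prevalence)
make EBIC-LASSO deliberately conservative; planted couplings between rare
nodes are often not recovered at realistic sample sizes, which is the
expected behaviour of the method rather than a defect.

## Problem sizes and defaults

Validation simulations use what small-cohort methodology work typically
uses: 50 replicates at n = 3000 for chain-graph recovery, 100 null
replicates at n = 1000, 300 replicates for sandwich CI coverage, 200 for
IPW de-biasing, 500 cohorts of n = 2000 for design-based coverage, 100
seeded planted-partition graphs for community recovery.  Bootstrap
defaults: B = 1000 for edge accuracy (B ≥ 50 enforced), B = 100 per
fraction for case dropping, CS threshold pair (0.7, 95%), configurable.

## Known limitations

- Nodewise pseudo-likelihood, not joint maximum likelihood; no Bayesian or
  moderated network variants.
- No small-sample cluster corrections (CR2/CR3) or Rao–Scott tests.
- Readmission is equidispersed (Poisson) around its mean; real counts are
  more dispersed.
- The single-chain Gibbs sampler trades exactness for scale above p = 15;
  thinned draws retain mild autocorrelation.
- Multiple imputation is intentionally out of scope: the pipeline is a
  complete-case + IPW design.
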