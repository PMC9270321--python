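# morbinet

Survey-weighted multimorbidity and hospitalisation analysis with
regularised graphical-model networks.

## What this package does

Ageing cohorts routinely ask two connected questions: *which factors are
associated with hospitalisation, readmission and length of stay?* and *how
do chronic conditions group together around those outcomes?*  `morbinet`
implements the full analysis chain for a complex-survey cohort of adults
aged 50+ — one row per participant, 19 binary morbidity indicators,
sociodemographic covariates, the three hospitalisation outcomes, and the
survey design (stratum, primary sampling unit, weight):

1. **Cohort IO & preparation** — schema-validated CSV reading/writing,
   complete-case exclusion accounting, inverse probability weighting (IPW)
   for the probability of being a complete case, an asset index (first
   principal component of 12 household-asset variables, cut into weighted
   quintiles), and the ordinal multimorbidity category (≤1 / 2 / ≥3
   conditions).
2. **Design-based estimation** — Horvitz–Thompson weighted prevalences with
   stratified between-PSU Taylor-linearised variances and logit-scale Wald
   95% CIs.
3. **Association models** — prevalence ratios (PR) from weighted Poisson
   regression with a log link and PSU-clustered robust (CR0 sandwich)
   variance; β coefficients for readmission and length of stay from
   weighted least squares on the hospitalised subset; the Goodman–Kruskal
   γ for ordinal cross-tables.
4. **Network estimation** — Ising models over binary nodes and mixed
   graphical models (binary/count/continuous) estimated nodewise with
   ℓ1-penalised GLMs, penalty selected per node by the Extended BIC
   (γ = 0.25), AND-rule symmetrisation.  An edge is a conditional
   association between two nodes controlling for all others.
5. **Network analysis** — walktrap community detection cut at maximum
   modularity, node predictability (variance explained / correct
   classification against intercept-only baselines), nonparametric
   bootstrap of edge weights, case-dropping correlation-stability (CS)
   coefficients, and the target-node flow layering used to read a network
   outward from hospitalisation.
6. **Synthetic cohorts** — a seeded generator producing cohorts with known
   ground truth (pairwise disease dependence graph, outcome coefficients,
   survey design, missingness mechanism) so every estimator above has a
   parameter-recovery test surface.  Real restricted survey data is never
   required.

### The core statistics

The disease network is a pairwise binary Markov random field
P(x) ∝ exp(Σᵢ τᵢxᵢ + Σᵢ<ⱼ θᵢⱼxᵢxⱼ).  Each node *j* is regressed on the rest
with coefficients minimising (1/n)·NLL + λ‖β‖₁; λ is chosen per node by

EBIC(λ) = −2·ℓ(λ) + df(λ)·log n + 2γ·df(λ)·log(p−1),  γ = 0.25,

and edge (i,j) is kept only if both directed coefficients are nonzero
(AND rule), with weight the mean of the two.  Prevalence ratios come from
the modified-Poisson approach: a log-link Poisson fit of the binary outcome
whose cluster-robust sandwich variance fixes the misspecified likelihood.

## Worked example

```python
import numpy as np
import morbinet as mn

cfg = mn.SimulationConfig(n_subjects=12000, p_diseases=10, seed=7)
cohort, truth = mn.generate_cohort(cfg)

analysis_vars = (cohort.schema.disease_names()
                 + cohort.schema.covariate_names() + ["hospitalisation"])
ipw = mn.compute_ipw(cohort, cohort.schema.covariate_names(), analysis_vars)
report, complete = mn.exclusion_report(cohort, analysis_vars)
print(report)

prev = mn.weighted_prevalence(complete, "hospitalisation")
print(f"prevalence {prev.estimate:.3f} [{prev.ci_low:.3f}, {prev.ci_high:.3f}]")

mm = mn.multimorbidity_category(complete).rename("multimorbidity")
res = mn.fit_poisson_pr(complete, "hospitalisation",
                        ["sex", "age_group", "multimorbidity"], extra=mm.to_frame())
print(res.to_frame()[["term", "level", "effect", "ci_low", "ci_high"]].round(3))

block = complete.df[cohort.schema.disease_names() + ["hospitalisation"]].astype(float)
net = mn.fit_ising(block)
print(net.edge_list().round(3))
part = mn.walktrap(np.abs(net.weights), labels=net.labels)
print(part.members())
```

prints

```
ExclusionReport(n_baseline=12000, n_missing=757, pct_missing=6.3, n_final=11243)
prevalence 0.101 [0.095, 0.107]
          term  level  effect  ci_low  ci_high
     intercept          0.075   0.066    0.084
           sex   male   1.465   1.298    1.652
     age_group  60-74   0.958   0.858    1.070
     age_group    75+   0.991   0.842    1.165
multimorbidity      2   1.574   1.368    1.811
multimorbidity    >=3   2.113   1.742    2.564
...
          node_i               node_j  weight  sign
high_cholesterol         back_problem   0.877     1
   heart_disease               stroke   0.389     1
          stroke arthritis_rheumatism   0.740     1
[['hypertension'], ['diabetes'], ['high_cholesterol', 'back_problem'],
 ['heart_disease', 'stroke', 'arthritis_rheumatism'], ['asthma'], ['copd'],
 ['osteoporosis'], ['hospitalisation']]
```

6.3% of rows are flagged by the missingness mechanism and excluded after
IPW; the weighted hospitalisation prevalence matches the generator's 10%
target; the PR for ≥3 conditions (2.11 [1.74, 2.56]) recovers the
generative gradient; and the estimated network finds the three strongest of
the five planted couplings (the two missed ones join conditions with 2–4%
prevalence, where EBIC-LASSO is deliberately conservative) — the walktrap
communities are exactly the recovered connected groups.

A full run — simulate → prepare → regress → network → analyse, with a run
manifest — is one command:

```
morbinet run --config run.yml
```

where `run.yml` can be as small as `simulate: {n_subjects: 5000, p_diseases: 12, seed: 1}`.
Stage-level commands (`morbinet simulate/prepare/regress/network/communities/
stability/flow`) expose the same functionality piecewise.

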