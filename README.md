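# ocdim

Hierarchical item-response modelling of lifetime obsessive–compulsive
symptom checklists.

Obsessive–compulsive disorder is heterogeneous: patients report very
different mixes of obsessions and compulsions over their lifetime, and
factor-analytic work has organised the 64-item clinician checklist into
five symptom domains (doubt/checking, contamination, symmetry/ordering,
hoarding, taboo thoughts). `ocdim` implements the complementary view that a
single underlying *OCD propensity* runs through all symptoms, with the
domains contributing extra, domain-specific variability on top. It is aimed
at psychiatric-genetics and clinical-psychometrics researchers who want to
score lifetime symptom data on a common dimension rather than by raw
symptom counts.

The package provides, as importable modules with a thin CLI (`ocdim`):

* **Latent-structure comparison** (`ocdim.latent_models`) — marginal-ML
  fits of a unidimensional 2PL, a correlated five-factor model, and a
  hierarchical **bifactor** model
  `P(y_ij=1) = σ(a0_j θ0 + as_j θ_d(j) + c_j)`, compared by AIC/BIC and
  likelihood-ratio tests, plus a leave-one-domain-out ablation and
  standardized loadings.
* **Bayesian testlet model** (`ocdim.testlet_mcmc`) — Metropolis-within-
  Gibbs estimation of `P(y_ij=1) = σ(a_j(θ_i − b_j − γ_{i,d(j)}))` with
  domain testlet effects `γ_{i,d} ~ N(0, σ_d²)`, Gelman–Rubin convergence
  checking (PSRF < 1.2 across ≥2 chains), per-symptom discrimination `a_j`
  and severity `b_j` with posterior SDs, and per-person propensity scores
  `θ_i` (mean 0, SD 1) with posterior SEs.
* **Graded response model** (`ocdim.severity_grm`) — one discrimination and
  four ordered thresholds per 0–4 clinician severity rating,
  `P(Y ≥ k) = σ(a(η − b_k))`, with information-based SEs and EAP scores.
* **Score agreement** (`ocdim.agreement`) — Spearman rank checks and a
  Bland–Altman procedure that flags persons whose checklist-derived and
  severity-derived scores differ by more than `z·sqrt(SE₁² + SE₂²)`.
* **Synthetic cohorts** (`ocdim.simulate`) — a generator with known ground
  truth standing in for the access-restricted clinical samples, and
  **data plumbing** (`ocdim.datasets`, `ocdim.pipeline`) for the delimited
  inputs, the zero-assignment rule for undiagnosed symptom-free persons,
  validation, and a seeded end-to-end pipeline.

The modelling choices are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the full study flow on a
synthetic 1000-person cohort. `python analysis/01_simulate_cohort.py`
writes the cohort and prints its heterogeneity summary:

```
cohort written to /root/pkg/results/data
  persons: 1000, items: 64
  symptomatic: 77.5%
  unique patterns among symptomatic: 82.7%
```

Roughly a quarter of persons are symptom-free (the undiagnosed stratum),
and almost every symptomatic person shows a unique lifetime pattern — the
heterogeneity that motivates scoring on a latent dimension instead of by
pattern. `python analysis/02_structure_comparison.py` then compares the
three structures:

```
            structure   loglik  n_parameters      aic      bic
       unidimensional -16631.1           128  33518.2  34146.4
   correlated_factors -16299.5           138  32874.9  33552.2
             bifactor -15957.6           192  32299.1  33241.4

preferred by BIC: bifactor
```

The hierarchical model wins on both criteria: the general dimension alone
is not enough, and neither are the five domains without it. The same
script's ablation and loadings show where the specific variance sits —
contamination (largest log-likelihood drop, 12 of 13 items with specific
loadings ≥ 0.35) and hoarding (2 of 2), mirroring the pattern reported for
real lifetime symptom data. `python analysis/03_testlet_model.py` fits the
Bayesian testlet model (2×4000 iterations) and prints

```
PSRF quantiles (50th, 97.5th) = (1.01, 1.04)
convergence pass (< 1.2): True
recovery: corr(b) = 0.978, corr(a) = 0.926
```

— the chains agree, and the posterior means recover the generating
discrimination/severity parameters. Scripts 04 and 05 fit the graded
response model to the clinician ratings and compare the two scoring routes:

```
Spearman(model score, raw symptom count) = 0.989
Spearman(checklist score, severity score) = 0.873
Bland-Altman agreement at z=1.96: 90.1% of 987 persons
```

The checklist score preserves the raw symptom-count ordering almost
perfectly while weighting discriminating symptoms more, tracks the
independently estimated severity score by rank, and agrees with it within
the joint 95% error bounds for nine of ten persons.

The same flow runs from a single config:

```bash
ocdim run-all --config run.yaml     # or: python -m ocdim.cli run-all ...
```

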