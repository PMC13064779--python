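# Methods

`ocdim` analyses lifetime obsessive–compulsive symptom data in which each
person reports the lifetime presence or absence of 64 specific obsessions and
compulsions (a clinician-administered checklist) and, when diagnosed,
receives ten 0–4 clinician ratings of worst-period severity. The package
asks three questions: does a single underlying OCD propensity organise the
64 symptoms beyond the five classical symptom domains (doubt/checking,
contamination, symmetry/ordering, hoarding, taboo thoughts); what propensity
level and discriminating power does each symptom carry; and how well do
checklist-derived and clinician-rating-derived person scores agree.

Because the motivating clinical samples are access-restricted, a synthetic
cohort generator with known ground truth stands in for them everywhere; all
empirical claims in this repository are claims about recovery of known
structure, not reproductions of the original samples' numbers.

## Latent-structure models

Three confirmatory structures are fitted to the binary checklist by marginal
maximum likelihood:

1. **Unidimensional 2PL.** P(y_ij = 1) = σ(a_j θ_i + c_j) with θ ~ N(0,1).
2. **Correlated five factors.** Each item loads only on its domain factor;
   the 5×5 factor correlation matrix is free (the spec of this model leaves
   the correlation structure open; freely correlated factors are the
   standard choice and nest the unidimensional model at the boundary).
3. **Hierarchical bifactor.** Every item loads on a general factor and on
   exactly one orthogonal domain-specific factor:
   P(y=1) = σ(a0_j θ0 + as_j θ_d(j) + c_j), all latents standard normal.
   Identification: latents mutually orthogonal with unit variance; specific
   slopes are sign-fixed per domain (the whole domain flips so its slope sum
   is positive); general slopes are unconstrained.

Estimation is Bock–Aitkin EM over fixed grids. One-dimensional and bifactor
integrals use **equally spaced normal-weighted nodes on [−6, 6]** (weights
∝ φ(x), normalised). This rule resolves the sharply concentrated posteriors
produced by high-discrimination items far better than Gauss–Hermite at equal
node counts; with Gauss–Hermite the fixture log-likelihoods moved by ~20
units between 21 and 42 nodes, while the equal-spacing rule is stable to
<0.01 at the defaults. Defaults: 101 nodes (one dimension), 41 general × 21
specific (bifactor). The correlated model uses a Gauss–Hermite tensor grid
(default 5 nodes/dimension, configurable as an accuracy/cost switch) mapped
through the Cholesky factor of the correlation matrix; its correlation
update uses the posterior second moment of the latent vector, renormalised
to unit diagonal with an eigenvalue floor of 1e−3 so the matrix stays
positive definite as correlations approach the unidimensional boundary
(slopes are rescaled accordingly).

M-steps are per-item penalised logistic regressions solved by Newton steps
with per-item backtracking, so the penalised expected log-likelihood never
decreases and EM ascent holds exactly (tracked on every iteration and
reported on the fit). A weak ridge (1e−4) stabilises all items; items with
no response variation get a stronger ridge (0.05) and are flagged. Graded
(ordinal) items use the cumulative-logit parameterisation with ordered
intercepts maintained through a log-increment reparameterisation and an
L-BFGS inner solver. Starting values: intercepts from logits of observed
endorsement rates (clipped to [0.02, 0.98]), slopes 1.0, specific slopes 0.5
(zero is a stationary saddle), factor correlations 0.3.

Model comparison reports log-likelihood, parameter count, AIC, BIC, ΔAIC,
ΔBIC and chi-square likelihood-ratio tests for nested pairs (unidimensional
inside bifactor; unidimensional inside correlated factors at the boundary).
The bifactor and correlated models are not nested in each other and get no
LRT. The leave-one-domain-out ablation refits the bifactor model with one
domain's specific slopes removed (those items keep their general loading),
warm-started from the full solution; the log-likelihood drop with df = items
in the domain measures that domain's contribution beyond the general trait.

Standardized loadings convert logit slopes to the normal metric,
λ_jk = (a_jk/1.702)/sqrt(1 + Σ_k (a_jk/1.702)²); a specific loading ≥ 0.35
is labelled "significant" (configurable; this is the lower bound of the
retained range reported for the clinical samples, used as a practical
threshold since no formal criterion is published).

For large structure-comparison simulations (n = 1500, 64 items, many seeds)
the analyses use reduced grids (61 nodes unidimensional, 21×15 bifactor,
4/dimension correlated) and looser tolerances (1e−3 / 1e−2): only the
ordering of fit indices matters there, and the index gaps between competing
structures are two orders of magnitude larger than the quadrature bias.

## Bayesian testlet model

The testlet response model adds a person×domain random effect to the 2PL:

    P(y_ij = 1) = σ(a_j (θ_i − b_j − γ_{i,d(j)}))
    θ_i ~ N(0,1) (fixed, for identification), γ_{i,d} ~ N(0, σ_d²)

b_j is the propensity level at which symptom j is endorsed with probability
one half ("severity"); a_j its discrimination; σ_d the extra within-domain
dependence. Testlet effects are independent across domains. The logistic
link uses scaling constant D = 1 throughout (a config switch exposes
D = 1.702 for normal-ogive comparability in the simulator).

Priors: ln a_j ~ N(0,1); b_j ~ N(0,4); σ_d² ~ Inverse-Gamma(1, 0.1);
all configurable. The IG(1, 0.1) default was chosen over the more common
IG(2, 1) because the latter places essentially no mass below σ ≈ 0.3 and
cannot shrink when a domain carries no testlet variance; IG(1, 0.1) both
shrinks correctly under the null (posterior median < 0.15 on an informative
fixture) and recovers σ_d ∈ {0.5, 1.0} within ~12% at n = 2000.

Sampling is blocked random-walk Metropolis within Gibbs — (θ | rest),
(γ_d | rest) per domain, (a | rest) on the log scale, (b | rest), and a
conjugate inverse-gamma draw for each σ_d² — with per-coordinate proposal
scales adapted by Robbins–Monro (step t^−0.66, target acceptance 0.44)
during burn-in only and frozen afterwards, preserving detailed balance. A
cached per-cell log-likelihood matrix makes each block a single vectorised
matrix evaluation. Chains are bit-reproducible given their seed.

Defaults follow the production settings of the motivating analysis: 40 000
iterations, 10 000 burn-in, 2 chains with overdispersed starts (chain c
draws θ from N(0, 2²), ln a from N(±0.5, 0.5²) with sign alternating by
chain, σ² starting at 0.5 or 2.0). Desk-scale analyses and tests use
4000/1000, which this sampler's mixing comfortably supports at n ≤ 2000.

Convergence uses the Gelman–Rubin potential scale reduction factor in its
classic between/within-chain variance (F-statistic) form, threshold 1.2,
monitored over all item slopes and severities plus the testlet SDs (not
individual θ_i); the report quotes the 50th and 97.5th percentiles over item
parameters. Summaries (item table, person scores) refuse to run on a failed
convergence report unless explicitly overridden, and the override is logged.
Person scores are pooled-chain posterior means with posterior SDs as SEs;
all-zero responders are flagged because the model cannot rank-order them
further below the zero-symptom threshold.

Person-level draws (θ, γ) can be thinned independently of item-parameter
draws (`person_thin`) to bound memory on large cohorts.

## Graded response model

Each severity rating has one discrimination and ordered thresholds
b_1 ≤ … ≤ b_4 with P(Y ≥ k) = σ(a(η − b_k)), η ~ N(0,1). Fitting is EM over
a 61-node equally spaced grid. Unobserved internal categories are merged
downward with the remapping recorded on the item; single-category items are
excluded with a warning. Standard errors come from the empirical
(outer-product-of-scores) information of the marginal likelihood — a
deterministic choice over bootstrap — mapped back to the natural
parameterisation by the delta method. Items with near-zero discrimination
or slope SEs above 1 are flagged `weak_discrimination`. EAP scores use a
61-node grid; persons with no administered rating fall back to the prior
(mean 0, SD 1) and are flagged.

For latent-structure comparison of the ten ratings, the graded link plugs
into the same EM machinery as the binary models; the two-factor split
assigns items 1–5 to obsessions and 6–10 to compulsions (the standard
instrument halves; configurable, since no split is published).

## Agreement analyses

Checklist (testlet) and severity (GRM) scores are compared per person by
the Bland–Altman construction with no gold standard: x = common mean of the
two estimates, y = difference (checklist − severity), and a person "agrees"
when |difference| ≤ z·sqrt(SE₁² + SE₂²) with z = 1.96 ("expected confidence
regions" read as 95%). Persons missing either score are excluded and
counted; a person with two zero SEs degenerates to an exact-equality check
and is flagged. Rank agreement uses Spearman correlation with average-rank
ties; constant vectors raise rather than returning a silent NaN. Plot
coordinates are exported as text so any plotting layer can add smoothing
(loess display is deliberately not reimplemented).

Under an equal-slope (Rasch-like) fitted model the endorsement count is a
sufficient statistic, so EAP scoring computes the score directly from the
count in that case; ties in the raw count then remain exact ties in the
score and Spearman correlation with raw counts is exactly 1.

## Synthetic cohort generator

The generator emulates the study conditions: 64 items in domain blocks of
16/13/15/2/18 (doubt–checking/contamination/symmetry–ordering/hoarding/
taboo; only three of those sizes are published — 16, 15, 18 — and hoarding
is two items, one obsession and one compulsion, fixing contamination at 13);
discriminations uniform on [0.5, 3.0]; severities uniform on [0.3, 2.7]
(matching the published b range 0.54–2.65); testlet SDs defaulting to 1.0
for contamination and hoarding and 0.5 elsewhere, the domains reported to
carry the strongest specific variance. Severity ratings come from a graded
model whose default bank mirrors published clinician-rating calibrations
(time/distress items most discriminating, a ≈ 2.9–3.2; resistance least,
a ≈ 1.4–1.6; thresholds rising to ~5 for the time items), with the
unpublished entries filled by mirroring their obsession/compulsion
counterparts. The severity trait is correlated 0.85 with the checklist
propensity by default (configurable; agreement-coverage checks use 1.0).

Persons are a two-stratum mixture: a diagnosed stratum with θ ~ N(0,1) and
an undiagnosed-relative stratum (37.5%, the cohort's relative fraction)
shifted down by 3.6 SD, calibrated once so that ~25% of persons endorse no
symptom, matching the reported fraction; severity interviews for
undiagnosed symptom-free persons are marked not-administered (so the
explicit zero-assignment rule has work to do), and 2% of rows are lost at
random. Recovery fixtures (parameter-recovery tests and the acceptance
script) set the unaffected fraction to 0 so the fitted θ ~ N(0,1) scale
matches the generating scale; the mixture fixture exercises realism, not
recovery.

What the generator does **not** emulate: family/sibling structure and
genetic relatedness, item-level missingness mechanisms other than
missing-completely-at-random rows, worst-period per-symptom severities and
ages of onset, and any drift between lifetime recall and current state.
Passing recovery tests therefore show the estimators work when their model
family is correct (plus the stratum misspecification noted above); they do
not validate the models against real clinical data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep each check
sharp but cheap: structure-recovery at n = 1500 with 10 seeds per
generating structure, ablation at n = 1000 with 10 seeds, testlet recovery
at n = 2000 with 2×4000-iteration chains, GRM recovery at n = 2000,
agreement coverage at n = 500 over 10 seeds. The pipeline's reduced MCMC
default is 4000/1000. EM convergence is declared on an absolute
log-likelihood change (default 1e−4); fits that hit the iteration cap are
flagged, never silently accepted. Probabilities are floored at 1e−300
before logs; Newton steps are clipped to ±2 before backtracking.

Per-stage pipeline seeds derive from the global seed by a fixed stride
(seed + 1 000 003 · stage-index, mod 2³¹), so any stage can be rerun
standalone and a rerun with the same config is bit-identical in every
delimited output.

## Known limitations

* The correlated-factors EM converges slowly near the unidimensional
  boundary (correlations → 1); runs there rely on the iteration cap and the
  non-convergence flag rather than tight tolerances.
* The 5-dimensional tensor grid at 4–5 nodes/dimension biases that model's
  log-likelihood down by tens of units; fine for structure ordering, not
  for absolute likelihood comparison against the other structures at
  near-tied fits.
* Specific slopes near zero are weakly identified (the likelihood is flat
  in their sign and nearly flat in magnitude); on truly unidimensional data
  their ML magnitudes settle around 0.3–0.4 rather than 0. Information
  criteria, not raw slope magnitudes, are the reliable signal of absent
  specific structure.
* MCMC standard errors for extreme all-zero responders reflect the prior as
  much as the data; the zero-symptom flag marks them.
* The acceptance script's recovery runs use 2×3000-iteration chains at
  n = 1500; the PSRF criterion is checked at these settings, and longer
  chains only improve it.
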