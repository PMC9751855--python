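# Methods

This note documents the models, rules and numerical choices behind
`comorbmap`, and what the synthetic-data tests do and do not demonstrate.

## Domain catalogue and impairment rules

The analysis is defined over a fixed registry of 20 test domains:
1 Touwen-derived (MND), 3 MABC-2 subtests, 6 SIPT tests and 10 NEPSY-II
subtests. Impairment means performance more than 1 SD below test norms on
the native scale:

| instrument | scale | impaired |
|---|---|---|
| Touwen | 8 binary dysfunction flags | ≥ 1 dysfunctional domain (simple MND = 1–2, complex > 2; pooled) |
| MABC-2 | standard score, integers 1–19 (mean 10, SD 3) | ≤ 7 |
| SIPT | z-score in [−3, 3] | < −1.0 |
| NEPSY-II | scaled score, integers 1–19 (mean 10, SD 3) | ≤ 7 |

Two rules deserve comment:

* **SIPT boundary.** A score of exactly −1.0 sits on the border between
  the typical and mild-dysfunction bands. The default is strict
  (−1.0 not impaired), matching the "below 1 SD" reading;
  `sipt_inclusive=True` flips the boundary. The choice affects only
  scores exactly at −1.0, a probability-zero event for continuous data.
* **Missingness.** A missing score (or an incomplete Touwen examination)
  yields no call: the cell is excluded from every denominator, burden
  count and pair count. MND is never classified from a partial flag set.
  This matches per-domain denominators that vary with data availability.

Two imputation operations mirror the handling of non-systematic
missingness in the data this design emulates: a group-median fill for
skewed score distributions, and a mean-of-available-siblings fill for
composite subtests. Both are opt-in, logged per cell, and idempotent.

## Burden profiles and relationship maps

A child's burden is the row sum of its impairment calls (0–20). The
relationship map of one group is the weighted co-occurrence graph: node
weight = impaired-child count per domain, edge weight = children impaired
in both endpoint domains, computed as `Mᵀ M` on the 0/1 call matrix. Maps
are reported at thresholds k ∈ {1, 5, 10}; "total impaired test pairs" is
the number of *distinct* pairs with weight ≥ k (bounded by C(20,2) = 190),
with the summed-incidence alternative exposed as a secondary statistic.
Triple relationships are per-child conjunctions (impaired in *all* listed
domains, all observed).

The figure layout fixes the registry order on a circle: Touwen/MABC-2/SIPT
clockwise along the upper semicircle, NEPSY-II anti-clockwise along the
lower, both reading left to right. Edge thickness is linear in the count
with a 0.5 pt minimum visible width. SVG output pins the hash salt and
strips the date so renders are byte-reproducible.

## Statistical layer

* **2×2 odds ratio**: cross-product ratio with Woolf log-scale CI
  (exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))); for a binary exposure this
  equals the binomial-logistic MLE exactly. Zero cells → NA (no silent
  continuity correction; Haldane–Anscombe +0.5 available explicitly).
* **Cumulative-logit OR**: proportional-odds model
  P(Y ≤ j | x) = expit(θⱼ − βx), fitted by damped Newton iteration with
  an analytic gradient and a finite-difference Hessian; with two outcome
  levels it reduces to binary logistic regression (verified to 1e-6
  against the cross-product ratio, and against an independent ordinal-
  regression implementation). |β| > 30 or non-convergence is reported as
  possible separation, never returned as a number.
* **Contingency tests**: Pearson χ² (no Yates correction), likelihood-
  ratio G = 2·Σ O·ln(O/E) with zero-observed cells contributing 0, and
  the two-sided Fisher exact test. All-zero margins are dropped with a
  warning and the df adjusted.
* **Rank/t tests**: Mann–Whitney U with midranks, tie correction and
  continuity correction; Welch t with Satterthwaite df; Cohen's d with
  the pooled (n−1)-weighted SD. All p-values are two-sided.
* **BCa intervals**: z₀ = Φ⁻¹(#{θ\*ᵦ < θ̂}/B) (clamped into
  (1/(B+1), B/(B+1)) with a warning when all resamples fall on one side);
  acceleration a from the jackknife skewness; endpoints are empirical
  quantiles at Φ(z₀ + (z₀ ± z_α)/(1 − a(z₀ ± z_α))). Identical resample
  statistics degenerate to a point interval with a warning. With z₀ = 0
  and a = 0 the interval is the percentile interval.
* **Bootstrapped t-test** (default B = 1,000): group-wise resampling of
  the mean difference with a BCa interval; the p-value studentises
  null-recentred resamples (both groups shifted to the grand mean) and
  uses the (1 + #exceedances)/(B + 1) estimator.
* **Wild-bootstrap regression** (default B = 2,000): OLS fit, then
  y\* = ŷ + w·ê with i.i.d. Rademacher signs (Mammen's two-point law as
  an option), refit per resample — vectorised as β\* = β̂ + X⁺(w∘ê) — and
  per-coefficient BCa intervals using leave-one-out coefficients from the
  hat-matrix update. With all signs +1 the resample reproduces the
  original fit exactly. Rademacher is the default weight law because it
  is the standard choice when no law is specified; the adjusted model's
  r² is reported as the usual adjusted r².
* **FDR**: Benjamini–Hochberg step-up q-values, one family per report
  table (the 20 impairment comparisons; the per-domain regression family),
  configurable at the pipeline level since family boundaries are a
  reporting convention.

In the adjusted regression model the covariates are sex, mother's
education, neonatal brain injury (IVH grade III–IV) and a combined
neonatal morbidity flag (sepsis/BPD/NEC). Mother's education enters as a
single ordinal 0/1/2 term, keeping the model at five predictors.
Covariate columns that are constant or collinear within the observed
subset of a small cohort are dropped with a logged warning rather than
aborting the fit.

## Synthetic cohort generator

The generator produces the *structure* the analysis assumes — two groups,
correlated impairments across instruments, native scales, sparse
missingness — from a deliberately minimal model: one latent liability
L ~ N(μ_g, 1) per child, μ_EPT = −shift, μ_TERM = 0.

* Score domains: z_d = δ_d + λ_d·L + √(1−λ_d²)·ε, mapped to the native
  scale (integer scales rounded and clipped to 1–19; SIPT clipped to
  [−3, 3]). The marginal deviate is exactly N(δ_d + λ_d·μ_g, 1), so the
  impairment probability is Φ(c_d − δ_d − λ_d·μ_g) with c_d the native
  cutoff on the z scale (−5/6 for integer scales via the rounding
  boundary at 7.5, −1 for SIPT).
* Touwen: each of the 8 domains is dysfunctional with probability
  Φ(α − s·L), independent given L, α = Φ⁻¹(base rate at L = 0); the MND
  marginal is integrated by 80-node Gauss–Hermite quadrature.
* Missingness is MCAR per score cell and per Touwen examination
  (default rate 0.10, chosen so observed denominators land in the range
  seen in the reference counts, roughly 44–56 of 56 and 33–36 of 37).
* Covariates are drawn from the reference study's marginal frequencies,
  independent of liability by default.

**Calibration.** Given targets (p_EPT, p_TERM) per domain, the term rate
fixes δ_d = c_d − Φ⁻¹(p_TERM) and the probit gap
g_d = Φ⁻¹(p_EPT) − Φ⁻¹(p_TERM) fixes λ_d·shift. The shared shift defaults
to the largest gap so every loading lies in [0, 1]; equal targets take the
smallest valid loading (0); infeasible targets (term > EPT under a
positive shift, or a gap exceeding a user-fixed shift) are reported per
domain, never clamped. The per-domain difficulty offsets δ_d are this
package's own extension of the single-factor model: without them the term
rate would be pinned at Φ(c_d) for every domain, and no loading could
match the observed spread of term rates (3–35%). The MND pair is solved
by nested Brent root-finding on the quadrature closed form. Zero
published counts are made feasible with a half-count (0.5/N ≈ 0.015)
continuity target. Published per-Touwen-domain rates are not separately
calibrated: the 8 flags share one base rate consistent with the MND
marginal, since the MND target already pins the aggregate and the
per-domain counts use a different denominator than the MND row.

**What the generator does and does not emulate.** It reproduces marginal
impairment rates, a realistic single-factor correlation structure
(inter-domain score correlation λ²), native scales and MCAR missingness.
It does *not* model multi-factor structure (e.g. instrument-specific
factors), item content, covariate–liability dependence, or
missingness-by-severity. Consequently, passing tests show the pipeline's
correctness and the direction/size of group separation under the stated
marginals — e.g. median mean burdens ≈ 5.4 vs 1.9 and a decisive
impaired-pair excess at n = 56/37 — but tail-shaped statistics (such as
the fraction of EPT children above the term-born maximum burden) depend
on correlation structure beyond the marginals and are reported as
computed, not tuned.

## Problem sizes and determinism

Every stochastic operation takes a seed and is reproducible bit-for-bit;
the pipeline derives all sub-seeds from one root seed and embeds a config
hash in every output file. Monte-Carlo checks use 5,000 children per
group for rate calibration (binomial SE ≈ 0.007), 200 seeds at the study
scale (56/37) for separation statistics, 200–300 simulations for
wild-bootstrap null coverage (n = 100, B = 500) and 500 replications for
BCa coverage of a normal mean (n = 100, B = 1,000) — sizes at which the
binomial noise of a coverage estimate (≈1–2 points) is small against the
tolerance being checked.

## Known limitations

* The proportional-odds fitter targets the two-sample design used here
  (binary regressor, few outcome levels); it is not a general ordinal
  regression engine.
* BCa intervals with B = 500 slightly undercover (≈94% empirically);
  the default B values (1,000/2,000) are recommended for reporting.
* The relationship-map renderer is a static figure, not an interactive
  graph view; layout is fixed by the registry, not data-driven.
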