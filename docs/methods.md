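# Methods

`hdpmeta` implements a case–control genetic-association meta-analysis for
the MTHFR polymorphisms (C677T, A1298C) and hypertensive disorders in
pregnancy (HDP), plus a "meta-prediction" layer that asks whether
study-level polymorphism frequencies and risks separate across ordinal
country-level air-pollution bands. This note records the models, the
defaults and the numerical choices, and what the synthetic validation
does and does not demonstrate.

## Data model

A study contributes genotype counts (homozygous wild-type / heterozygote
/ homozygous variant) for a case arm and a control arm, plus covariates:
country, ethnic group, HDP subtype (preeclampsia–eclampsia, gestational
hypertension, mixed), an air-pollution band, a quality score (0–28) and
year. Pollution bands code national death rates from air pollution per
million: 1 (≤50), 2 (51–100), 3 (101–250), 4 (251–400), 5 (≥401). Band 1
is merged into band 2 before analysis and band 5 is essentially
unpopulated in this literature, so the analysed levels are 2, 3, 4. The
country→band lookup is the user's responsibility: the level arrives as an
input column.

## Genetic contrasts and effect measures

Five contrasts group genotypes into "exposed": TT, CT, CC, the dominant
carrier grouping TT+CT, and the non-recessive CC+CT. The denominator is
always the arm total, so the risk ratio is the standardized

RR = (a/n₁) / (c/n₂),  var(log RR) = 1/a − 1/n₁ + 1/c − 1/n₂,

with a exposed among n₁ cases and c exposed among n₂ controls. The odds
ratio from the same 2×2 is a(n₂−c)/(c(n₁−a)) with the usual Woolf
variance. When any of {a, n₁−a, c, n₂−c} is zero a Haldane–Anscombe
constant (default 0.5, configurable) is added to all four cells, raising
n₁ and n₂ by 1. A study with zero exposed in both arms carries no ratio
information and is excluded from that contrast's pooling, always with a
logged reason. Confidence intervals are Wald on the log scale with
z = 1.959964.

## Pooling and model selection

Fixed-effect pooling is inverse-variance on the log scale
(w_i = 1/se_i²). Heterogeneity: Cochran Q = Σw_i(θ_i − θ̂)², df = k−1,
I² = max(0, 100(Q−df)/Q), and the DerSimonian–Laird moment estimator
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)). Random-effects pooling re-weights by
1/(se_i²+τ²). The model is selected per contrast by the heterogeneity
test: random when the Q p-value is strictly below the heterogeneity
alpha (default 0.05), fixed otherwise; a single study always pools fixed
and is reported flagged as single-study evidence rather than a pooled
estimate. When τ² truncates to zero the random-effects result equals the
fixed-effect result exactly; single-estimate pooling returns the
estimate verbatim (no weight round-trip, preserving bit-identity).

Mantel–Haenszel fixed pooling and weighted Egger variants are documented
alternatives, not implemented. Publication-bias diagnostics are the
classic (unweighted) Egger regression of θ_i/se_i on 1/se_i — the
intercept's t test with k−2 df — and funnel-plot coordinates (effect,
se, fixed-effect center line); no trim-and-fill.

## Hardy–Weinberg screening

Controls are screened with the 1-df Pearson chi-square against expected
proportions (1−p)², 2p(1−p), p² at the observed variant-allele
frequency p. Monomorphic arms are flagged, not tested. Departures flag
a study (possible genotyping error or stratification) but never drop it;
the flag travels to the run manifest. An exact test is out of scope.

## Meta-prediction over pollution levels

Study-level outcomes are the arm percentages of TT, CT, CC and TT+CT
and the per-study RRs of the four contrasts (locus-neutral names
`pct_variant_case` … `rr_carrier`). For each outcome the package
enumerates the no-split model and every contiguous binary cut of the
observed levels ({2}|{3,4} and {2,3}|{4} for three levels — no
non-contiguous splits), fits the group-means normal model, and scores
each candidate by

AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1),   k = #groups + 1,

counting one common variance beside the group means. The argmin wins;
ties break toward fewer groups; a candidate whose leaf would hold fewer
than 5 studies is excluded; tree depth is one split by design (the
reported analyses are single binary partitions). A perfect fit maps to
−∞, which orders correctly. All candidates' AICc values are returned as
a ledger, not just the winner.

Tukey–Kramer comparisons accompany every partition: pooled within-group
MSE with N−g error df, pair SE = √(MSE(1/nᵢ+1/nⱼ)), adjusted p from the
studentized-range distribution at q = |Δ|√2/SE, and simultaneous 95%
CIs from the same critical value. With two groups this reduces exactly
to the pooled two-sample t test. The trend fit is a least-squares
polynomial (default quadratic) of outcome on the numeric level, degree
reduced when fewer levels are observed; the heat map is a count matrix
over (level, value-bin) cells with half-open bins, the last bin closed,
and out-of-grid values clipped into edge bins with a log entry.

## Synthetic-study generator

The generator draws, per study i (counter-based substream
`SeedSequence(seed, spawn_key=(i,))`, so growing a collection never
reshuffles earlier studies): an allele frequency p ~ U(interval), arm
sizes, and a random effect b ~ N(0, τ²) truncated at ±4σ. Control
genotype probabilities follow the F-parameterization
((1−p)²+Fp(1−p), 2p(1−p)(1−F), p²+Fp(1−p)); F = 0 is Hardy–Weinberg.

The case arm is ascertained retrospectively with the variant and
heterozygote frequencies set to RR_TT·e^b and RR_CT·e^b times their
control frequencies and the wild-type absorbing the complement. This
"absorb" construction makes the nominal genotype relative risks the
*exact* marginal estimands of the analysis (case-arm TT frequency is
exactly RR_TT times the control frequency at b = 0), which is what a
parameter-recovery test should recover; a proportional-renormalized
tilt would instead shrink the marginal ratio by the normalizing constant
(≈1.64 for a nominal 1.75 at p = 0.3) and make "truth" model-dependent.
The implied wild-type RR is (1 − RR_TT q_TT − RR_CT q_CT)/q_CC < 1 when
carriers are enriched — as in real case–control data. Configurations
whose carrier mass could exceed 1 anywhere in the parameter range
(evaluated at the highest p and b = +4σ) are rejected before any
sampling.

The pollution gradient tilts the case-arm carrier genotypes on the
log-odds scale by γ·(level−2) ("linear", default) or by γ only at level
4 ("step"), renormalized. Counts are multinomial draws.

Canonical scenarios (module functions, used by the validation suites and
the acceptance script):

- `calibration_null_config` — k = 10 studies, 200/arm, p ∈ [0.2, 0.4],
  no effects: type-I-error checks.
- `recovery_config` — k = 40, 500/arm, p = 0.30, RR_TT = 1.75,
  τ = 0.1: the East Asian effect-size regime.
- `gradient_config` — 12 studies per level, 200–500/arm,
  p ∈ [0.25, 0.35], step gradient γ = 0.55: raises the expected case-arm
  carrier percentage by ≈13 points at level 4 (the reported ~12-point
  contrast regime) while leaving controls untouched.

What the generator does *not* emulate: literature-selection bias (no
publication-bias generator), per-contrast random effects (one shared
perturbation per study), covariate confounding between ethnicity and
pollution level, and genotyping error. Passing the synthetic suites
therefore demonstrates internal statistical correctness and power under
the stated regimes, not robustness to those real-data pathologies.

## Validation problem sizes

The packaged suites use: 1000 null collections for heterogeneity
calibration (rejection rate expected in [0.03, 0.07] at α = 0.05); all
5000 control arms of 500 null collections for Hardy–Weinberg calibration
(the 1-df chi-square's true rate at n = 200 is ≈0.050); 100 seeds for RR
recovery (|pooled − 1.75| ≤ 0.15 expected in ≥90%); 100 seeds for
gradient detection ({2,3}|{4} chosen and Tukey 4-vs-2 adjusted p < 0.05
expected in ≥80%, control arm fully non-significant in ≥90%). Oracle
property tests run ≥200 randomized instances per statistic against
brute-force transcriptions (Q, τ², Egger intercept, HWE chi-square,
AICc, exhaustive split enumeration) and against scipy's independent
Tukey HSD implementation.

## Numerical and reporting choices

- Percentages are computed at full precision and rounded half-up to two
  decimals only at report time; pooled effects and CI bounds print at
  two decimals.
- The heterogeneity model-selection boundary is strict (p exactly equal
  to alpha selects fixed).
- Country names are stored verbatim and matched case-insensitively for
  stratification; unknown ethnic-group labels are rejected at parse
  time rather than coerced.
- "Varied" direction countries are those whose study-level TT RRs
  straddle (or touch) 1, or whose RR is undefined; the alternative
  CI-containing-1 rule is a documented extension, not the default.
- Report output is deterministic: fixed column orders, UNIX newlines,
  sorted JSON keys — identical inputs produce byte-identical tables.

## Known limitations

Published pooled effect sizes from this literature are not reproducible
from the pooled margins alone (they are study-weighted, and the original
software's estimator defaults are unknown); the package validates its
estimators against oracles and synthetic truth instead. The partition
layer handles a single ordinal predictor at depth one; multi-covariate
trees and deeper recursion are out of scope. No GIS/choropleth or any
other rendering is produced — all outputs are coordinate/count tables.
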