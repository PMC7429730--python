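# Methods

## Estimands and measures

The indicator is binary coverage (ANC4+) among women with a recent live
birth. For a subgroup *g* of an equity stratifier, the estimand is the
population coverage `p_g` (reported in %, 0–100, converting internal
probabilities only at the boundary — every published number in this
setting is on the percentage scale). The national average `μ` is the
coverage over the whole denominator population.

The four summary measures compare an advantaged **reference** subgroup
with a **comparison** subgroup or with `μ`:

| measure | definition | scale | type |
|---|---|---|---|
| D | `p_ref − p_comp` | pp | absolute, simple |
| R | `p_ref / p_comp` | unitless | relative, simple |
| PAR | `p_ref − μ` | pp | absolute, complex |
| PAF | `100·PAR/μ` | % of μ | relative, complex |

Reference rules: for *ordered* and *binary* dimensions the reference is
fixed a priori at the advantaged end (richest quintile, secondary+
education, urban) and the comparison is the opposite extreme —
intermediate categories (e.g. primary education) are skipped. For
*non-ordered* dimensions (region) the reference is the best-performing
subgroup and the comparison the worst-performing one, determined from the
estimates; exact ties are broken by category-list order and flagged.
Because the indicator is favourable (higher is better), the reference is
the best-off group and PAR is nonnegative in truth; a negative estimated
PAR can only arise from sampling noise and is truncated to 0 with a
`truncated` flag (silent truncation would hide the event from users).

A measure is *significant* at the 95% level when its uncertainty interval
excludes the null value: 0 for D/PAR/PAF, 1 for R. No multiplicity
adjustment is applied across the 16 dimension×measure cells; each call is
a marginal statement, matching standard equity-monitoring reporting.

## Survey-weighted estimation

Subgroup coverage is the weighted ratio `p_g = Σ w y / Σ w` over the
subgroup's records. Variance uses Taylor linearization under the
with-replacement PSU approximation — the standard convention for DHS-type
stratified two-stage designs: the linearized score
`z_i = w_i (y_i − p_g)/W_g` is totalled per cluster, and

```
Var(p_g) = Σ_h  n_h/(n_h−1) · Σ_{c∈h} (z_hc − z̄_h)²
```

over strata *h* with `n_h ≥ 2` clusters. Domain (subgroup) estimation
keeps all clusters in the sums; clusters without members of the subgroup
contribute zero totals. Single-cluster strata contribute nothing to the
variance (the generator never produces them; real inputs with lonely PSUs
therefore understate variance rather than crash — a deliberate choice for
robustness, consistent with how survey software treats certainty PSUs).

Confidence intervals for proportions are Wald intervals on the logit
scale, `expit(logit(p) ± z·se_p/(p(1−p)))`, mapped back to %. This
produces the asymmetric bounds seen in published DHS tables and respects
the [0, 100] range. At boundary estimates (0 or 100) the logit transform
degenerates; a Wilson score interval built from the subgroup's unweighted
size is substituted and flagged in `ci_method`. `z` is fixed at 1.96 for
the 95% level (the convention the published tables use); other levels use
the exact normal quantile.

Published subgroup tables (estimate, 95% interval, population) are
ingested by back-deriving `se = (upper − lower)/(2·1.96)` — a symmetric
approximation to an asymmetric interval; the printed bounds themselves are
kept verbatim. Subgroups with unweighted n < 25 are flagged as suppressed
(configurable), never silently dropped.

## Uncertainty intervals for the measures

All measure intervals are delta-method Wald intervals at level `z`:

- **D**: `D ± z·√(se_ref² + se_comp²)`, treating the two subgroups as
  independent (they contain disjoint women; with clustered designs the
  shared-cluster covariance is small and slightly conservative to ignore).
- **R**: log-scale delta method,
  `R·exp(∓z·√((se_ref/p_ref)² + (se_comp/p_comp)²))`, keeping the interval
  positive.
- **PAR**: delta method on `p_ref − μ`. Since μ contains the reference
  subgroup with population share `s_ref`, the two estimates covary:
  `Cov(p_ref, μ) ≈ s_ref·Var(p_ref)`. With the full subgroup set
  available, μ is expanded as the share-weighted subgroup mean (subgroups
  independent), giving
  `Var(PAR) = (1−s_ref)²·Var(p_ref) + Σ_{g≠ref} s_g²·Var(p_g)`;
  with only an external `se(μ)` the equivalent
  `Var(p_ref) + Var(μ) − 2·s_ref·Var(p_ref)` is used. A naive
  independence variant (`method="independent"`) is kept because the exact
  machinery behind published HEAT intervals is not documented; the
  covariance-corrected form is the default as the naive form visibly
  over-widens the interval.
- **PAF**: the PAR bounds multiplied by `100/μ`. Treating μ as fixed in
  this scaling makes the PAR→PAF coupling an exact identity of the
  implementation (and the published PAR/PAF interval pairs satisfy it to
  printed precision), at the cost of ignoring the μ-uncertainty in the
  denominator — the published tables behave the same way.

When PAR is truncated to 0, the interval is kept (upper bound clipped up
to ≥ 0) so the significance call still reflects the evidence.

## The synthetic survey generator

Real unit records for this analysis are access-restricted, so correctness
is demonstrated on simulated data with a known truth surface.

**What it emulates.** A stratified two-stage cluster sample: strata are
region × residence (36 with the default 18 regions, mirroring designs that
report national, regional and urban/rural estimates), with an equal number
of clusters per stratum (small regions oversampled, as in real DHS
frames) and a fixed number of women per cluster. Wealth and education are
drawn per woman from residence-specific category probabilities (urban
strata skew rich/educated), so stratifiers are correlated as in real data.
The outcome follows a logistic model with additive log-odds effects for
wealth, education, residence and region plus a normal cluster random
intercept; the default effects loosely track the observed Angola
gradients (poorest ≈ 34% → richest ≈ 88%, Luanda high / Cuanza Sul low).
Design weights are the stratum population-to-sample share ratio times
mean-one lognormal noise.

**Truth.** Cell probabilities are the *marginal* outcome probabilities
`E[expit(η + σ_c U)]`, computed by 40-node Gauss–Hermite quadrature, so
truth and data-generating process agree exactly under cluster
heterogeneity, and every subgroup truth is a share-weighted mean of cell
truths — the aggregation identities between subgroup truths and the
national truth hold in exact arithmetic.

**Key parameters** (defaults, chosen to emulate the Angola analysis
sample):

| parameter | default | why |
|---|---|---|
| regions / strata | 18 × urban/rural = 36 | study design |
| clusters × women per stratum | 14 × 17 (n = 8,568) | ≈ the 8,492-woman analysis denominator |
| cluster random-effect sd `σ_c` | 0.25 logits | mild intra-cluster correlation (≈ 0.02 latent ICC), typical of DHS coverage indicators |
| weight dispersion (lognormal σ) | 0.25 | realistic unequal weights without extreme tails |
| wealth/education effects | monotone, 0→2.2 / 0→1.1 logits | reproduce observed-scale gradients |

**Reproducibility.** One integer seed drives a single generator consumed
in a documented order (cluster effects, wealth uniforms, education
uniforms, outcome uniforms, weight noise — each one vectorized draw over
records in stratum-major order), so identical configs give byte-identical
record streams.

**What it does not emulate** — and hence what passing tests do not show
about real data: the actual Angolan sampling frame and non-response
adjustment; within-cluster correlation of wealth/education (only
residence-level composition differences are modelled); interviewer or
recall measurement error in the ANC4+ outcome; item missingness. Tests on
this generator validate the estimation and measure machinery, not the
substantive Angola findings.

## Study sizes used in the validation runs

- **Benchmark**: exact recomputation of all 16 published measures from the
  28 published subgroup rows and μ = 61.4464; tolerance ±0.02 on the
  printed scale (chosen to absorb the 2-decimal rounding of the printed
  inputs), runtime well under a second.
- **Calibration**: 500 replicates of a 6-region (12-strata, 24 clusters ×
  70 women ≈ 20,160-record) survey for bias, interval coverage and — with
  a flat truth surface — false-positive rate. Fewer regions than the full
  18 keep every subgroup large enough that coverage estimates are
  informative at this size.
- **Recovery**: 100 replicates of a large, low-noise design (8 strata ×
  150 clusters × 90 women = 108,000; `σ_c = 0`, weight σ = 0.1) for the
  1-pp all-subgroup recovery check; at realistic noise and n ≈ 50k a
  per-region sampling SE alone exceeds 1 pp, so the consistency check is
  run where sampling spread does not swamp the band.

## Numerical and degenerate-input choices

- Percentage scale end to end; probabilities only inside the interval
  transform and the generator.
- `se = 0` yields the degenerate interval (estimate, estimate).
- Zero comparison coverage makes R an explicit error (never ±inf).
- Exact estimate ties in non-ordered contrast selection: first category in
  list order wins, `tied` flag set.
- Grouped estimation accumulates in record order (numpy `bincount`), so it
  reproduces a per-record summation bit for bit.
- Published-table round-trips preserve printed digits; unit-record CSV
  reads use round-trip float parsing.

## Known limitations

- The with-replacement PSU approximation slightly overstates variance when
  sampling fractions are large; no finite-population correction is
  applied (none is available in published DHS tables either).
- PAR/PAF intervals depend on an approximation to `Cov(p_ref, μ)`; the
  exact covariance requires unit-level data, and even there the published
  intervals' provenance is undocumented, so point estimates — not interval
  widths — are the benchmarked quantities.
- The back-derived `se` from a printed asymmetric interval is a symmetric
  approximation; it is accurate for mid-range estimates and degrades near
  the boundaries.
- Suppression (n < 25) flags estimates but the measures will still use a
  flagged extreme category for ordered dimensions if told to; the
  non-ordered selector excludes suppressed subgroups.
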