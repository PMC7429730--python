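# anc-equity

Survey-weighted disaggregation and WHO-style inequality summary measures
for binary health-coverage indicators, built around the 2015–16 Angola
analysis of antenatal-care coverage (ANC4+: at least four antenatal visits
during the most recent pregnancy).

Health-equity monitoring asks not just *how much* coverage a country has
but *who* gets it. Coverage is disaggregated by equity stratifiers —
wealth quintile, maternal education, urban/rural residence, subnational
region — and the gap between subgroups is summarised with four measures:

- **Difference** `D = p_ref − p_comp`, in percentage points (absolute,
  simple);
- **Ratio** `R = p_ref / p_comp`, unitless (relative, simple);
- **Population Attributable Risk** `PAR = p_ref − μ`: the absolute gain in
  national coverage if every subgroup attained the reference level
  (absolute, complex);
- **Population Attributable Fraction** `PAF = 100·PAR/μ`: the same gain as
  a percentage of current national coverage (relative, complex).

Here `p_ref` is the coverage of the advantaged reference subgroup
(richest quintile, secondary+ education, urban; for the non-ordered region
dimension, the best-performing region), `p_comp` the opposite extreme, and
`μ` the survey-weighted national average. Each measure carries a 95%
uncertainty interval; inequality is called significant when the interval
excludes 0 (D, PAR, PAF) or 1 (R).

The package provides, for an audience of epidemiologists and
health-systems analysts:

- **`estimation`** — survey-weighted subgroup prevalence with
  Taylor-linearized variance for stratified two-stage cluster designs
  (with-replacement PSU approximation) and logit-scale Wald intervals;
  or ingestion of already-published subgroup tables with standard errors
  back-derived from the printed intervals.
- **`measures`** — the four summary measures with delta-method uncertainty
  intervals and significance calls.
- **`synthetic`** — a DHS-like survey generator (stratified two-stage
  cluster sample, correlated stratifiers, cluster-level random effects,
  dispersed weights) with an exactly known truth surface, used to validate
  every estimator.
- **`pipeline` / `cli`** — end-to-end runs from unit records or from
  published subgroup summaries, plus a benchmark that reproduces the
  published Angola measure table from the published subgroup table.
- Packaged fixtures: the published Angola subgroup-coverage table (28
  subgroup rows + national average μ = 61.4464 over 8,492 women) and the
  published 16-cell measure table.

## Worked example

```python
from anc_equity import table1_fixture, study_dimensions, compute_measures

grouped, mu = table1_fixture()          # published subgroup estimates + mu
dim = study_dimensions()["economic_status"]
for r in compute_measures(grouped["economic_status"], dim, mu):
    print(f"{r.measure:>3} = {r.estimate:6.2f}  "
          f"95% UI ({r.ui_lower:.2f}, {r.ui_upper:.2f})  "
          f"significant={r.significant}")
```

prints

```
  D =  54.15  95% UI (49.58, 58.72)  significant=True
  R =   2.59  95% UI (2.32, 2.90)  significant=True
PAR =  26.73  95% UI (24.11, 29.35)  significant=True
PAF =  43.51  95% UI (39.24, 47.77)  significant=True
```

i.e. ANC4+ coverage among women in the richest wealth quintile is 54.15
percentage points higher (2.59 times higher) than among the poorest, and
national coverage would rise by 26.7 pp — 43.5% of its current level — if
all women attained richest-quintile coverage. The same is available from
the shell:

```sh
anc-equity benchmark                    # diff all 16 measures vs print
anc-equity simulate --seed 1 --out-dir scratch/sim
anc-equity measures --input scratch/sim/survey.csv --level unit
```

The numbered scripts under `analysis/` run the full study in order:
simulate a survey (`01`), disaggregate coverage (`02`), compute the
measures (`03`), benchmark them against the published table (`04`), and
calibrate the estimators by Monte Carlo (`05`). Each writes its tables
under `results/`.

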