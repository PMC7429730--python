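"""Monte-Carlo calibration of the estimators and measure intervals.

These studies generate many synthetic surveys with a known coverage
surface and measure, across replicates: the bias of every subgroup
estimator, the empirical coverage of the 95% subgroup intervals and of the
Difference interval, and — under a null configuration where every cell has
the same true coverage — the false-positive rate of the D and R
significance calls.

The study design is a reduced version of the default survey: 6 regions x
urban/rural (12 strata) with 24 clusters of 70 women per stratum, about
20,000 women per replicate, with the default cluster heterogeneity and
weight dispersion switched on.  Fewer regions than the full 18 keep every
subgroup large enough for coverage estimates to be meaningful at this
sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dimensions import DimensionSpec, study_dimensions
from .estimation import national_average, weighted_prevalence
from .measures import difference, ratio, select_contrast
from .synthetic import (
    OutcomeModel,
    SyntheticConfig,
    _truth_table,
    generate_survey,
    truth_summary,
)

SIM_REGIONS = ("Alfa", "Bravo", "Charlie", "Delta", "Echo", "Foxtrot")
_SIM_SHARES = dict(zip(SIM_REGIONS, (0.25, 0.20, 0.15, 0.15, 0.15, 0.10)))
_SIM_URBAN = dict(zip(SIM_REGIONS, (0.80, 0.60, 0.50, 0.45, 0.65, 0.35)))
_SIM_EFFECTS = dict(zip(SIM_REGIONS, (0.80, 0.30, 0.00, -0.30, 0.40, -0.60)))


def simulation_config(seed: int = 0, null: bool = False) -> SyntheticConfig:
    """Study design for the calibration runs (n = 20,160 women).

    With ``null=True`` every covariate effect is zero and the intercept sits
    at logit(0.5), so all subgroup truths coincide: D = 0 and R = 1 exactly.
    """
    if null:
        model = OutcomeModel(
            intercept=0.0,
            wealth_effects=(0.0,) * 5,
            education_effects=(0.0,) * 3,
            residence_effects=(0.0, 0.0),
            region_effects={r: 0.0 for r in SIM_REGIONS},
        )
    else:
        model = OutcomeModel(region_effects=dict(_SIM_EFFECTS))
    return SyntheticConfig(
        regions=SIM_REGIONS,
        region_population_share=dict(_SIM_SHARES),
        urban_share_by_region=dict(_SIM_URBAN),
        n_clusters_per_stratum=24,
        n_women_per_cluster=70,
        outcome_model=model,
        seed=seed,
    )


@dataclass
class CalibrationResult:
    """Replicate-averaged calibration summaries."""

    n_reps: int
    subgroups: pd.DataFrame   # dimension, subgroup, truth, mean_estimate, bias, coverage
    contrasts: pd.DataFrame   # dimension, d_truth, d_coverage, d_significant_rate,
                              # r_truth, r_coverage, r_significant_rate

    @property
    def mean_subgroup_coverage(self) -> float:
        return float(self.subgroups["coverage"].mean())

    @property
    def max_abs_bias(self) -> float:
        return float(self.subgroups["bias"].abs().max())


#: ordered/binary dimensions whose extreme contrast is checked per replicate
CONTRAST_DIMENSIONS = ("economic_status", "education", "residence")


def run_calibration(
    n_reps: int = 500,
    seed: int = 0,
    config: SyntheticConfig | None = None,
    contrast_dimensions: tuple[str, ...] = CONTRAST_DIMENSIONS,
) -> CalibrationResult:
    """Run `n_reps` synthetic surveys and summarise estimator calibration.

    Replicate r uses seed ``seed + r``; the truth surface is identical
    across replicates (only the draws vary).
    """
    cfg = simulation_config(seed) if config is None else config
    dims = study_dimensions(regions=list(cfg.regions))
    truth = _truth_table(cfg)
    truths: dict[str, list[tuple[str, float]]] = {
        name: truth_summary(truth, dim) for name, dim in dims.items()
    }

    sub_index: list[tuple[str, str, float]] = [
        (name, sub, t) for name, pairs in truths.items() for sub, t in pairs
    ]
    est_sum = np.zeros(len(sub_index))
    cover = np.zeros(len(sub_index))
    d_truth, r_truth = {}, {}
    d_cover = {d: 0 for d in contrast_dimensions}
    d_sig = {d: 0 for d in contrast_dimensions}
    r_cover = {d: 0 for d in contrast_dimensions}
    r_sig = {d: 0 for d in contrast_dimensions}
    for d in contrast_dimensions:
        pairs = dict(truths[d])
        dim = dims[d]
        d_truth[d] = pairs[dim.advantaged_end] - pairs[dim.disadvantaged_end]
        r_truth[d] = pairs[dim.advantaged_end] / pairs[dim.disadvantaged_end]

    for r in range(n_reps):
        records, _ = generate_survey(replace(cfg, seed=seed + r))
        by_dim = {
            name: weighted_prevalence(records, dim, suppress_below=0)
            for name, dim in dims.items()
        }
        lookup = {(n, e.subgroup): e for n, ests in by_dim.items() for e in ests}
        for j, (name, sub, t) in enumerate(sub_index):
            e = lookup[(name, sub)]
            est_sum[j] += e.estimate
            cover[j] += e.ci_lower <= t <= e.ci_upper
        for dname in contrast_dimensions:
            c = select_contrast(by_dim[dname], dims[dname])
            d = difference(c.reference, c.comparison)
            rr = ratio(c.reference, c.comparison)
            d_cover[dname] += d.ui_lower <= d_truth[dname] <= d.ui_upper
            d_sig[dname] += d.significant
            r_cover[dname] += rr.ui_lower <= r_truth[dname] <= rr.ui_upper
            r_sig[dname] += rr.significant

    subgroups = pd.DataFrame(
        [(name, sub, t, est_sum[j] / n_reps, est_sum[j] / n_reps - t,
          cover[j] / n_reps)
         for j, (name, sub, t) in enumerate(sub_index)],
        columns=["dimension", "subgroup", "truth", "mean_estimate", "bias",
                 "coverage"])
    contrasts = pd.DataFrame(
        [(d, d_truth[d], d_cover[d] / n_reps, d_sig[d] / n_reps,
          r_truth[d], r_cover[d] / n_reps, r_sig[d] / n_reps)
         for d in contrast_dimensions],
        columns=["dimension", "d_truth", "d_coverage", "d_significant_rate",
                 "r_truth", "r_coverage", "r_significant_rate"])
    return CalibrationResult(n_reps=n_reps, subgroups=subgroups, contrasts=contrasts)


def recovery_config(seed: int = 0) -> SyntheticConfig:
    """Large low-noise design for consistency checks (n = 108,000 women).

    Cluster heterogeneity and weight dispersion are turned down so that the
    Monte-Carlo spread of every subgroup estimator is a small fraction of a
    percentage point and a 1 pp recovery band is informative.
    """
    regions = SIM_REGIONS[:4]
    return SyntheticConfig(
        regions=regions,
        region_population_share={r: _SIM_SHARES[r] for r in regions},
        urban_share_by_region={r: _SIM_URBAN[r] for r in regions},
        n_clusters_per_stratum=150,
        n_women_per_cluster=90,
        outcome_model=OutcomeModel(
            region_effects={r: _SIM_EFFECTS[r] for r in regions},
            cluster_sd=0.0),
        weight_dispersion=0.1,
        seed=seed,
    )
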