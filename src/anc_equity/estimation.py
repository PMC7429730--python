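"""Survey-weighted prevalence estimation for complex (stratified, clustered) designs.

Subgroup coverage of a binary indicator is estimated as the weighted ratio

    p_g = sum_{i in g} w_i y_i / sum_{i in g} w_i            (reported in %)

with a Taylor-linearized variance under the standard with-replacement PSU
approximation: the linearized score z_i = w_i (y_i - p_g) / W_g is totalled
per cluster, and the variance is the between-cluster variance of those
totals within each stratum,

    Var(p_g) = sum_h  n_h/(n_h - 1)  sum_{c in h} (z_hc - zbar_h)^2,

where n_h counts the clusters of stratum h.  Subgroup (domain) estimation
keeps every cluster in the sum — clusters without members of g contribute
zero totals — which is the convention survey packages use.

Confidence intervals are Wald intervals on the logit scale mapped back to
the percentage scale, which produces the asymmetric bounds typical of
published DHS tables; a Wilson score interval is used as fallback for
estimates at the 0/100 boundary where the logit transform degenerates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .dimensions import DimensionSpec

#: conventional critical value for the 95% level (fixed, matching DHS practice)
Z_95 = 1.96

#: subgroups with fewer unweighted observations than this are flagged
DEFAULT_SUPPRESS_BELOW = 25


def z_value(level: float) -> float:
    """Normal critical value for a two-sided interval at `level` (in %)."""
    if not 0 < level < 100:
        raise ValueError(f"confidence level must be in (0, 100), got {level}")
    if level == 95:
        return Z_95
    return float(norm.ppf(0.5 + level / 200.0))


@dataclass
class SubgroupEstimate:
    """Coverage estimate for one subgroup of one dimension, on the % scale."""

    dimension: str
    subgroup: str
    estimate: float          # % in [0, 100]
    se: float                # % (symmetric-scale standard error)
    ci_lower: float          # %
    ci_upper: float          # %
    population: float        # subgroup size (unweighted count or weighted total)
    suppressed: bool = False
    ci_method: str = "logit_wald"
    n_unweighted: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 100.0:
            raise ValueError(
                f"{self.dimension}/{self.subgroup}: estimate {self.estimate} outside [0, 100]"
            )
        if self.se < 0:
            raise ValueError(f"{self.dimension}/{self.subgroup}: negative SE")
        if not self.ci_lower <= self.estimate + 1e-9 or not self.estimate <= self.ci_upper + 1e-9:
            raise ValueError(
                f"{self.dimension}/{self.subgroup}: interval ({self.ci_lower}, "
                f"{self.ci_upper}) does not bracket estimate {self.estimate}"
            )
        if self.population < 0:
            raise ValueError(f"{self.dimension}/{self.subgroup}: negative population")


@dataclass
class NationalAverage:
    """The survey-weighted national coverage (the measures' reference level mu)."""

    estimate: float          # %
    se: float | None         # %; None when published without an interval
    population: float
    ci_lower: float | None = None
    ci_upper: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 100.0:
            raise ValueError(f"national average {self.estimate} outside [0, 100]")
        if self.se is not None and self.se < 0:
            raise ValueError("national average has negative SE")


# ---------------------------------------------------------------------------
# linearized variance core (numpy arrays, probabilities on the 0-1 scale)
# ---------------------------------------------------------------------------

def _domain_ratio_estimates(
    y: np.ndarray,
    w: np.ndarray,
    stratum: np.ndarray,
    cluster: np.ndarray,
    domain: np.ndarray,
    n_domains: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted domain means and linearized variances.

    Parameters are integer-coded: `stratum` in [0, H), `cluster` in [0, C)
    globally (each cluster belongs to exactly one stratum), `domain` in
    [0, n_domains).  Returns (p, var, W, n) with p the weighted mean per
    domain, var its linearized variance (both on the scale of y), W the
    weighted domain totals and n the unweighted domain counts.
    """
    W = np.bincount(domain, weights=w, minlength=n_domains)
    if np.any(W <= 0):
        empty = np.flatnonzero(W <= 0)
        raise ValueError(f"empty domain(s) {empty.tolist()}: no weighted observations")
    Y = np.bincount(domain, weights=w * y, minlength=n_domains)
    p = Y / W
    n = np.bincount(domain, minlength=n_domains)

    # linearized score per record, totalled by (cluster, domain)
    z = w * (y - p[domain]) / W[domain]
    C = int(cluster.max()) + 1
    T = np.bincount(cluster * n_domains + domain, weights=z,
                    minlength=C * n_domains).reshape(C, n_domains)

    # stratum of each cluster (clusters are nested in strata)
    clus_strat = np.full(C, -1, dtype=np.int64)
    clus_strat[cluster] = stratum
    H = int(stratum.max()) + 1
    n_h = np.bincount(clus_strat, minlength=H)

    var = np.zeros(n_domains)
    for h in range(H):
        nh = n_h[h]
        if nh < 2:
            continue  # single-PSU stratum: no between-cluster contribution
        Th = T[clus_strat == h]
        dev = Th - Th.mean(axis=0, keepdims=True)
        var += nh / (nh - 1) * np.sum(dev * dev, axis=0)
    return p, var, W, n


def _codes(values: pd.Series, categories: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if categories is None:
        codes, uniques = pd.factorize(values, sort=False)
        return codes.astype(np.int64), list(uniques)
    cat = pd.Categorical(values, categories=list(categories))
    codes = cat.codes.astype(np.int64)
    if (codes < 0).any():
        bad = sorted(set(values[codes < 0].astype(str)))
        raise ValueError(f"values {bad} not among categories {list(categories)}")
    return codes, list(categories)


def _design_arrays(records: pd.DataFrame, outcome: str, weight: str,
                   stratum: str, cluster: str) -> tuple[np.ndarray, ...]:
    for col in (outcome, weight, stratum, cluster):
        if col not in records.columns:
            raise ValueError(f"records are missing required column {col!r}")
    y = records[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome column {outcome!r} must be binary 0/1")
    w = records[weight].to_numpy(dtype=float)
    if not (w > 0).all():
        raise ValueError(f"weight column {weight!r} must be strictly positive")
    s, _ = _codes(records[stratum])
    # cluster ids are only unique within stratum; code them globally
    key = records[stratum].astype(str) + "\x1f" + records[cluster].astype(str)
    c, _ = _codes(key)
    return y, w, s, c


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def weighted_prevalence(
    records: pd.DataFrame,
    dimension: DimensionSpec,
    *,
    outcome: str = "anc4",
    weight: str = "weight",
    stratum: str = "stratum_id",
    cluster: str = "cluster_id",
    level: float = 95.0,
    suppress_below: int = DEFAULT_SUPPRESS_BELOW,
    population: str = "unweighted",
) -> list[SubgroupEstimate]:
    """Survey-weighted coverage per subgroup of `dimension`, with 95% CIs.

    Subgroups with fewer than `suppress_below` unweighted observations are
    flagged ``suppressed`` (DHS reporting convention) but still returned.
    `population` selects whether the reported subgroup size is the
    unweighted record count or the weighted total.
    """
    if len(records) == 0:
        raise ValueError("records are empty")
    if population not in ("unweighted", "weighted"):
        raise ValueError("population must be 'unweighted' or 'weighted'")
    col = dimension.colname
    if col not in records.columns:
        raise ValueError(f"records are missing dimension column {col!r}")
    if records[col].isna().any():
        raise ValueError(f"dimension column {col!r} has missing values")

    y, w, s, c = _design_arrays(records, outcome, weight, stratum, cluster)
    d, cats = _codes(records[col], dimension.categories)
    present = np.flatnonzero(np.bincount(d, minlength=len(cats)) > 0)
    # re-code to the present categories only (a category can be unobserved)
    remap = -np.ones(len(cats), dtype=np.int64)
    remap[present] = np.arange(len(present))
    p, var, W, n = _domain_ratio_estimates(y, w, s, c, remap[d], len(present))

    out: list[SubgroupEstimate] = []
    for j, ci in enumerate(present):
        est = 100.0 * p[j]
        se = 100.0 * math.sqrt(max(var[j], 0.0))
        lo, hi, method = _interval_with_method(est, se, level, n_eff=float(n[j]))
        out.append(SubgroupEstimate(
            dimension=dimension.name,
            subgroup=cats[ci],
            estimate=est,
            se=se,
            ci_lower=lo,
            ci_upper=hi,
            population=float(n[j]) if population == "unweighted" else float(W[j]),
            suppressed=bool(n[j] < suppress_below),
            ci_method=method,
            n_unweighted=int(n[j]),
        ))
    return out


def national_average(
    records: pd.DataFrame,
    *,
    outcome: str = "anc4",
    weight: str = "weight",
    stratum: str = "stratum_id",
    cluster: str = "cluster_id",
    level: float = 95.0,
    population: str = "unweighted",
) -> NationalAverage:
    """Survey-weighted national coverage mu over all records, with its SE."""
    if len(records) == 0:
        raise ValueError("records are empty")
    y, w, s, c = _design_arrays(records, outcome, weight, stratum, cluster)
    d = np.zeros(len(records), dtype=np.int64)
    p, var, W, n = _domain_ratio_estimates(y, w, s, c, d, 1)
    est = 100.0 * p[0]
    se = 100.0 * math.sqrt(max(var[0], 0.0))
    lo, hi, _ = _interval_with_method(est, se, level, n_eff=float(n[0]))
    return NationalAverage(
        estimate=est, se=se,
        population=float(n[0]) if population == "unweighted" else float(W[0]),
        ci_lower=lo, ci_upper=hi,
    )


def _interval_with_method(
    estimate: float, se: float, level: float, n_eff: float | None = None
) -> tuple[float, float, str]:
    z = z_value(level)
    if se == 0.0 and 0.0 < estimate < 100.0:
        return estimate, estimate, "degenerate"
    if estimate <= 0.0 or estimate >= 100.0:
        # logit transform degenerates at the boundary; use a Wilson score
        # interval built from the (effective) sample size instead
        if n_eff is None or n_eff <= 0:
            raise ValueError(
                "boundary estimate needs an effective sample size for the Wilson fallback"
            )
        p = estimate / 100.0
        denom = 1.0 + z * z / n_eff
        centre = (p + z * z / (2 * n_eff)) / denom
        half = (z / denom) * math.sqrt(p * (1 - p) / n_eff + z * z / (4 * n_eff * n_eff))
        return 100.0 * (centre - half), 100.0 * (centre + half), "wilson"
    p = estimate / 100.0
    s = se / 100.0
    se_logit = s / (p * (1.0 - p))
    lo = 100.0 * float(expit(logit(p) - z * se_logit))
    hi = 100.0 * float(expit(logit(p) + z * se_logit))
    return lo, hi, "logit_wald"


def estimate_interval(
    estimate: float, se: float, level: float = 95.0, n_eff: float | None = None
) -> tuple[float, float]:
    """Interval around a coverage estimate (%), logit-Wald by default.

    `se` is the symmetric-scale standard error in percentage points.  For
    boundary estimates (0 or 100) a Wilson score interval is substituted,
    which requires `n_eff`; `weighted_prevalence` records which method was
    used in ``SubgroupEstimate.ci_method``.

    >>> estimate_interval(50.0, 5.0)
    (40.32..., 59.67...)
    """
    if se < 0:
        raise ValueError("se must be nonnegative")
    lo, hi, _ = _interval_with_method(estimate, se, level, n_eff=n_eff)
    return lo, hi


def summaries_from_published(
    rows: pd.DataFrame, *, level: float = 95.0
) -> list[SubgroupEstimate]:
    """Build SubgroupEstimates from published (estimate, CI, population) rows.

    The standard error is back-derived from the printed interval as
    (upper - lower) / (2 z), a symmetric approximation; the printed bounds
    themselves are preserved verbatim.  Expects columns
    dimension, subgroup, estimate, ci_lower, ci_upper, population.
    """
    required = {"dimension", "subgroup", "estimate", "ci_lower", "ci_upper", "population"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"summary rows are missing columns {sorted(missing)}")
    z = z_value(level)
    out = []
    for row in rows.itertuples(index=False):
        if not (row.ci_lower <= row.estimate <= row.ci_upper):
            raise ValueError(
                f"malformed interval for subgroup {row.subgroup!r}: "
                f"({row.ci_lower}, {row.ci_upper}) around {row.estimate}"
            )
        out.append(SubgroupEstimate(
            dimension=str(row.dimension),
            subgroup=str(row.subgroup),
            estimate=float(row.estimate),
            se=(float(row.ci_upper) - float(row.ci_lower)) / (2.0 * z),
            ci_lower=float(row.ci_lower),
            ci_upper=float(row.ci_upper),
            population=float(row.population),
            ci_method="published",
        ))
    return out
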