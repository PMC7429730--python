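"""WHO-style inequality summary measures: Difference, Ratio, PAR, PAF.

Given subgroup coverage estimates for one equity stratifier and the
national average mu, four summary measures quantify the inequality between
an advantaged reference subgroup and a comparison subgroup:

    D   = p_ref - p_comp                (absolute, simple; percentage points)
    R   = p_ref / p_comp                (relative, simple; unitless)
    PAR = p_ref - mu                    (absolute, complex; percentage points)
    PAF = 100 * PAR / mu                (relative, complex; % of current mu)

For ordered/binary dimensions the reference is the a-priori advantaged
category and the comparison the opposite extreme (richest vs poorest,
secondary+ vs no education, urban vs rural); for non-ordered dimensions the
best- and worst-performing subgroups are used.  PAR is the absolute gain in
national coverage if every subgroup attained the reference level; for a
favourable indicator it is truncated at zero (negative values only arise
from estimation noise) and flagged.

95% uncertainty intervals: D uses independent-SE combination; R a
log-scale delta method; PAR a delta method on p_ref - mu that subtracts the
covariance induced by the reference subgroup's population share within mu
(Cov(p_ref, mu) ~= s_ref Var(p_ref)); PAF bounds are the PAR bounds scaled
by 100/mu, so the PAR/PAF coupling holds exactly by construction.  A
measure is called significant when its interval excludes the null value
(0 for D/PAR/PAF, 1 for R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .dimensions import DimensionSpec
from .estimation import NationalAverage, SubgroupEstimate, z_value

MEASURES = ("D", "R", "PAR", "PAF")
PAR_METHODS = ("covariance", "independent")


@dataclass
class InequalityResult:
    """One summary measure for one dimension, with its uncertainty interval."""

    dimension: str
    measure: str             # D | R | PAR | PAF
    estimate: float          # pp (D, PAR), % (PAF) or unitless ratio (R)
    ui_lower: float
    ui_upper: float
    reference_subgroup: str
    comparison_subgroup: str = ""   # empty for PAR/PAF (contrast is vs mu)
    significant: bool = False
    level: float = 95.0
    truncated: bool = False
    tie_broken: bool = False

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not self.ui_lower <= self.estimate + 1e-9:
            raise ValueError(
                f"{self.dimension}/{self.measure}: lower bound {self.ui_lower} "
                f"above estimate {self.estimate}")
        if not self.estimate <= self.ui_upper + 1e-9:
            raise ValueError(
                f"{self.dimension}/{self.measure}: upper bound {self.ui_upper} "
                f"below estimate {self.estimate}")
        if self.measure == "R" and self.estimate <= 0:
            raise ValueError("ratio must be positive")
        if self.measure in ("PAR", "PAF") and self.estimate < 0:
            raise ValueError(f"{self.measure} must be nonnegative after truncation")

    @property
    def null_value(self) -> float:
        return 1.0 if self.measure == "R" else 0.0


@dataclass(frozen=True)
class Contrast:
    """Reference/comparison subgroups selected for the simple measures."""

    reference: SubgroupEstimate
    comparison: SubgroupEstimate
    tied: bool = False


def _require_se(est: SubgroupEstimate) -> float:
    if est.se is None or math.isnan(est.se):
        raise ValueError(f"subgroup {est.subgroup!r} has no standard error")
    return est.se


def select_contrast(
    estimates: Sequence[SubgroupEstimate], dimension: DimensionSpec
) -> Contrast:
    """Pick the reference and comparison subgroups for one dimension.

    Ordered/binary: the a-priori advantaged extreme vs the opposite extreme
    (intermediate categories are skipped).  Non-ordered: highest- vs
    lowest-estimate subgroup among the non-suppressed ones; exact ties are
    broken by category-list order and flagged.
    """
    by_label = {e.subgroup: e for e in estimates}
    usable = [e for e in estimates if not e.suppressed]
    if len(usable) < 2:
        raise ValueError(
            f"dimension {dimension.name!r}: fewer than 2 non-suppressed subgroups")
    if dimension.semantics in ("ordered", "binary"):
        ref_label = dimension.advantaged_end
        comp_label = dimension.disadvantaged_end
        for label in (ref_label, comp_label):
            if label not in by_label:
                raise ValueError(
                    f"dimension {dimension.name!r}: extreme category {label!r} "
                    "has no estimate")
        return Contrast(by_label[ref_label], by_label[comp_label])
    # non-ordered: estimate-driven extremes, ties broken by category order
    order = {c: i for i, c in enumerate(dimension.categories)}
    usable_sorted = sorted(usable, key=lambda e: order.get(e.subgroup, len(order)))
    best = max(usable_sorted, key=lambda e: e.estimate)
    worst = min(usable_sorted, key=lambda e: e.estimate)
    tied = (sum(e.estimate == best.estimate for e in usable) > 1
            or sum(e.estimate == worst.estimate for e in usable) > 1)
    return Contrast(best, worst, tied=tied)


# ---------------------------------------------------------------------------
# interval formulas
# ---------------------------------------------------------------------------

def _par_variance(
    reference: SubgroupEstimate,
    mu: NationalAverage,
    peers: Sequence[SubgroupEstimate] | None,
    method: str,
) -> float:
    """Variance of p_ref - mu on the % scale.

    With the full subgroup set (`peers`) mu is treated as the share-weighted
    mean of the subgroups, assumed mutually independent, giving
    Var = (1-s_ref)^2 Var(ref) + sum_{g != ref} s_g^2 Var(g) under the
    covariance method.  Without peers an externally estimated Var(mu) is
    used with the share-based covariance correction Cov = s_ref Var(ref).
    """
    if method not in PAR_METHODS:
        raise ValueError(f"unknown PAR interval method {method!r}")
    var_ref = _require_se(reference) ** 2
    if peers is not None:
        pops = [p.population for p in peers]
        total = sum(pops)
        if total <= 0:
            raise ValueError("peer subgroups carry no population")
        shares = {p.subgroup: p.population / total for p in peers}
        s_ref = shares.get(reference.subgroup, 0.0)
        var_mu = sum((p.population / total) ** 2 * _require_se(p) ** 2 for p in peers)
        cov = s_ref * var_ref if method == "covariance" else 0.0
        return max(var_ref + var_mu - 2.0 * cov, 0.0)
    if mu.se is None or math.isnan(mu.se):
        raise ValueError(
            "PAR interval needs either the full subgroup set (peers) or an "
            "SE for the national average")
    s_ref = reference.population / mu.population if mu.population else 0.0
    cov = s_ref * var_ref if method == "covariance" else 0.0
    return max(var_ref + mu.se**2 - 2.0 * cov, 0.0)


def measure_uncertainty(
    measure: str,
    reference: SubgroupEstimate,
    comparison: SubgroupEstimate | None = None,
    mu: NationalAverage | None = None,
    peers: Sequence[SubgroupEstimate] | None = None,
    level: float = 95.0,
    par_method: str = "covariance",
) -> tuple[float, float]:
    """Uncertainty interval for one summary measure (see module docstring)."""
    z = z_value(level)
    if measure == "D":
        if comparison is None:
            raise ValueError("D needs a comparison subgroup")
        half = z * math.hypot(_require_se(reference), _require_se(comparison))
        d = reference.estimate - comparison.estimate
        return d - half, d + half
    if measure == "R":
        if comparison is None:
            raise ValueError("R needs a comparison subgroup")
        if comparison.estimate <= 0 or reference.estimate <= 0:
            raise ValueError("ratio interval needs strictly positive estimates")
        r = reference.estimate / comparison.estimate
        se_log = math.hypot(_require_se(reference) / reference.estimate,
                            _require_se(comparison) / comparison.estimate)
        return r * math.exp(-z * se_log), r * math.exp(z * se_log)
    if measure in ("PAR", "PAF"):
        if mu is None:
            raise ValueError(f"{measure} needs the national average")
        half = z * math.sqrt(_par_variance(reference, mu, peers, par_method))
        par_est = reference.estimate - mu.estimate
        lo, hi = par_est - half, par_est + half
        if measure == "PAF":
            if mu.estimate <= 0:
                raise ValueError("PAF undefined for mu <= 0")
            scale = 100.0 / mu.estimate
            return lo * scale, hi * scale
        return lo, hi
    raise ValueError(f"unknown measure {measure!r}")


# ---------------------------------------------------------------------------
# the four measures
# ---------------------------------------------------------------------------

def difference(
    reference: SubgroupEstimate,
    comparison: SubgroupEstimate,
    level: float = 95.0,
    tie_broken: bool = False,
) -> InequalityResult:
    """D = reference - comparison, in percentage points."""
    lo, hi = measure_uncertainty("D", reference, comparison, level=level)
    res = InequalityResult(
        dimension=reference.dimension, measure="D",
        estimate=reference.estimate - comparison.estimate,
        ui_lower=lo, ui_upper=hi,
        reference_subgroup=reference.subgroup,
        comparison_subgroup=comparison.subgroup,
        level=level, tie_broken=tie_broken,
    )
    res.significant = is_significant(res)
    return res


def ratio(
    reference: SubgroupEstimate,
    comparison: SubgroupEstimate,
    level: float = 95.0,
    tie_broken: bool = False,
) -> InequalityResult:
    """R = reference / comparison, unitless."""
    if comparison.estimate <= 0:
        raise ValueError(
            f"ratio undefined: comparison subgroup {comparison.subgroup!r} "
            "has zero coverage")
    lo, hi = measure_uncertainty("R", reference, comparison, level=level)
    res = InequalityResult(
        dimension=reference.dimension, measure="R",
        estimate=reference.estimate / comparison.estimate,
        ui_lower=lo, ui_upper=hi,
        reference_subgroup=reference.subgroup,
        comparison_subgroup=comparison.subgroup,
        level=level, tie_broken=tie_broken,
    )
    res.significant = is_significant(res)
    return res


def par(
    reference: SubgroupEstimate,
    mu: NationalAverage,
    peers: Sequence[SubgroupEstimate] | None = None,
    level: float = 95.0,
    method: str = "covariance",
) -> InequalityResult:
    """PAR = reference - mu, truncated at 0 (flagged) when negative."""
    est = reference.estimate - mu.estimate
    lo, hi = measure_uncertainty(
        "PAR", reference, mu=mu, peers=peers, level=level, par_method=method)
    truncated = est < 0
    if truncated:
        est = 0.0
        hi = max(hi, 0.0)
    res = InequalityResult(
        dimension=reference.dimension, measure="PAR",
        estimate=est, ui_lower=min(lo, est), ui_upper=hi,
        reference_subgroup=reference.subgroup,
        level=level, truncated=truncated,
    )
    res.significant = is_significant(res)
    return res


def paf(par_result: InequalityResult, mu: NationalAverage) -> InequalityResult:
    """PAF = 100 * PAR / mu; bounds are the PAR bounds scaled by 100/mu."""
    if par_result.measure != "PAR":
        raise ValueError("paf() takes a PAR result")
    if mu.estimate <= 0:
        raise ValueError("PAF undefined for mu <= 0")
    scale = 100.0 / mu.estimate
    res = InequalityResult(
        dimension=par_result.dimension, measure="PAF",
        estimate=par_result.estimate * scale,
        ui_lower=par_result.ui_lower * scale,
        ui_upper=par_result.ui_upper * scale,
        reference_subgroup=par_result.reference_subgroup,
        level=par_result.level, truncated=par_result.truncated,
    )
    res.significant = is_significant(res)
    return res


def is_significant(result: InequalityResult) -> bool:
    """True when the interval excludes the null (0 for D/PAR/PAF, 1 for R)."""
    return not (result.ui_lower <= result.null_value <= result.ui_upper)


def compute_measures(
    estimates: Sequence[SubgroupEstimate],
    dimension: DimensionSpec,
    mu: NationalAverage,
    level: float = 95.0,
    par_method: str = "covariance",
    contrast: Contrast | None = None,
) -> list[InequalityResult]:
    """All four measures for one dimension, in the order D, R, PAR, PAF.

    PAR/PAF use the best-performing extreme as reference; for ordered and
    binary dimensions that is the advantaged end, for non-ordered the
    highest-estimate subgroup — the same reference `select_contrast` picks.
    """
    c = contrast if contrast is not None else select_contrast(estimates, dimension)
    d = difference(c.reference, c.comparison, level=level, tie_broken=c.tied)
    r = ratio(c.reference, c.comparison, level=level, tie_broken=c.tied)
    p = par(c.reference, mu, peers=estimates, level=level, method=par_method)
    f = paf(p, mu)
    return [d, r, p, f]
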