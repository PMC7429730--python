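"""Summary measures D, R, PAR, PAF: printed examples, identities, properties."""

import math

import pytest
from hypothesis import given, strategies as st

from anc_equity import (
    NationalAverage,
    SubgroupEstimate,
    difference,
    is_significant,
    measure_uncertainty,
    paf,
    par,
    ratio,
    select_contrast,
    study_dimensions,
)
from anc_equity.measures import InequalityResult

MU = NationalAverage(estimate=61.4464, se=None, population=8492)


def _sub(label, estimate, se=1.0, dimension="economic_status", population=1000.0):
    lo, hi = max(estimate - 1.96 * se, 0.0), min(estimate + 1.96 * se, 100.0)
    return SubgroupEstimate(dimension=dimension, subgroup=label,
                            estimate=estimate, se=se, ci_lower=lo,
                            ci_upper=hi, population=population)


# --- printed-value examples -------------------------------------------------

def test_difference_printed_values():
    assert difference(_sub("rich", 88.18), _sub("poor", 34.03)).estimate == \
        pytest.approx(54.15, abs=1e-9)
    assert difference(_sub("urban", 73.76), _sub("rural", 39.41)).estimate == \
        pytest.approx(34.35, abs=1e-9)


def test_ratio_printed_values():
    assert ratio(_sub("rich", 88.18), _sub("poor", 34.03)).estimate == \
        pytest.approx(2.59, abs=0.005)
    assert ratio(_sub("urban", 73.76), _sub("rural", 39.41)).estimate == \
        pytest.approx(1.87, abs=0.005)


def test_par_printed_values():
    assert par(_sub("sec+", 81.34), MU, peers=[_sub("sec+", 81.34)]).estimate == \
        pytest.approx(19.89, abs=0.005)
    assert par(_sub("Luanda", 83.23), MU, peers=[_sub("Luanda", 83.23)]).estimate == \
        pytest.approx(21.78, abs=0.005)


def test_paf_printed_values():
    p = par(_sub("rich", 88.18), MU, peers=[_sub("rich", 88.18)])
    f = paf(p, MU)
    assert f.estimate == pytest.approx(43.52, abs=0.02)
    # printed bound-scaling identity: PAR bounds (24.65, 28.83) -> PAF bounds
    assert 24.65 * 100 / 61.4464 == pytest.approx(40.12, abs=0.02)
    assert 28.83 * 100 / 61.4464 == pytest.approx(46.92, abs=0.02)


def test_d_interval_from_back_derived_ses_matches_print():
    rich = _sub("rich", 88.18, se=(90.61 - 85.23) / 3.92)
    poor = _sub("poor", 34.03, se=(37.82 - 30.44) / 3.92)
    d = difference(rich, poor)
    assert d.ui_lower == pytest.approx(49.59, abs=0.05)
    assert d.ui_upper == pytest.approx(58.70, abs=0.05)
    assert d.significant


# --- contrast selection -----------------------------------------------------

def test_select_contrast_ordered_and_binary(dims, table1):
    grouped, _ = table1
    c = select_contrast(grouped["economic_status"], dims["economic_status"])
    assert (c.reference.subgroup, c.comparison.subgroup) == (
        "Quintile 5 (richest)", "Quintile 1 (poorest)")
    c = select_contrast(grouped["education"], dims["education"])
    assert (c.reference.subgroup, c.comparison.subgroup) == (
        "Secondary school +", "No education")
    c = select_contrast(grouped["residence"], dims["residence"])
    assert (c.reference.subgroup, c.comparison.subgroup) == ("Urban", "Rural")


def test_select_contrast_non_ordered_uses_extremes(dims, table1):
    grouped, _ = table1
    c = select_contrast(grouped["region"], dims["region"])
    assert c.reference.subgroup == "Luanda"
    assert c.reference.estimate == 83.23
    assert c.comparison.subgroup == "Cuanza Sul"
    assert not c.tied


def test_select_contrast_tie_broken_by_category_order(dims):
    a = _sub("Luanda", 50.0, dimension="region")
    b = _sub("Bengo", 50.0, dimension="region")
    c = select_contrast([a, b], dims["region"])
    assert c.tied
    # Luanda precedes Bengo in the category list
    assert c.reference.subgroup == "Luanda"


def test_select_contrast_requires_two_usable_subgroups(dims):
    only = _sub("Urban", 70.0, dimension="residence")
    sup = SubgroupEstimate(dimension="residence", subgroup="Rural",
                           estimate=40.0, se=1.0, ci_lower=38.0,
                           ci_upper=42.0, population=10, suppressed=True)
    with pytest.raises(ValueError, match="non-suppressed"):
        select_contrast([only, sup], study_dimensions()["residence"])


# --- significance and edge cases -------------------------------------------

def test_significance_rules():
    sig = InequalityResult("d", "D", 54.15, 49.59, 58.70, "rich", "poor")
    assert is_significant(sig)
    r = InequalityResult("d", "R", 1.05, 0.9, 1.2, "rich", "poor")
    assert not is_significant(r)
    p = InequalityResult("d", "PAR", 1.0, -0.5, 2.0, "rich")
    assert not is_significant(p)


def test_zero_ratio_denominator_is_error():
    with pytest.raises(ValueError, match="ratio undefined"):
        ratio(_sub("a", 50.0), _sub("b", 0.0, se=0.0))


def test_par_truncated_at_zero_when_reference_below_mu():
    res = par(_sub("ref", 55.0), MU, peers=[_sub("ref", 55.0)])
    assert res.estimate == 0.0
    assert res.truncated
    assert res.ui_upper >= 0.0
    f = paf(res, MU)
    assert f.estimate == 0.0 and f.truncated


def test_degenerate_zero_se_interval():
    a, b = _sub("a", 70.0, se=0.0), _sub("b", 40.0, se=0.0)
    d = difference(a, b)
    assert (d.ui_lower, d.ui_upper) == (d.estimate, d.estimate)
    r = ratio(a, b)
    assert r.ui_lower == pytest.approx(r.estimate) == pytest.approx(r.ui_upper)


def test_missing_se_raises_with_subgroup_name():
    bad = _sub("Quintile 3", 50.0)
    bad.se = float("nan")
    with pytest.raises(ValueError, match="Quintile 3"):
        measure_uncertainty("D", bad, _sub("b", 40.0))


# --- properties -------------------------------------------------------------

@given(p=st.floats(1.0, 99.0), n=st.integers(2, 6))
def test_null_collapse(p, n):
    """Equal subgroup estimates: D = 0, R = 1, PAR = 0, PAF = 0 exactly."""
    subs = [_sub(f"g{i}", p, se=0.5, population=100) for i in range(n)]
    mu = NationalAverage(estimate=p, se=0.5, population=100 * n)
    assert difference(subs[0], subs[1]).estimate == 0.0
    assert ratio(subs[0], subs[1]).estimate == 1.0
    pr = par(subs[0], mu, peers=subs)
    assert pr.estimate == 0.0
    assert paf(pr, mu).estimate == 0.0


@given(ref1=st.floats(30.0, 80.0), bump=st.floats(0.0, 19.0),
       comp=st.floats(5.0, 29.0))
def test_monotone_in_reference(ref1, bump, comp):
    """Raising the reference estimate weakly increases all four measures."""
    mu = NationalAverage(estimate=25.0, se=1.0, population=2000)
    lo = _sub("ref", ref1)
    hi = _sub("ref", ref1 + bump)
    cmp_ = _sub("comp", comp)
    assert difference(hi, cmp_).estimate >= difference(lo, cmp_).estimate
    assert ratio(hi, cmp_).estimate >= ratio(lo, cmp_).estimate
    p_lo = par(lo, mu, peers=[lo, cmp_])
    p_hi = par(hi, mu, peers=[hi, cmp_])
    assert p_hi.estimate >= p_lo.estimate
    assert paf(p_hi, mu).estimate >= paf(p_lo, mu).estimate


@given(ref=st.floats(35.0, 95.0), comp=st.floats(5.0, 34.0),
       se_r=st.floats(0.1, 3.0), se_c=st.floats(0.1, 3.0),
       mu_est=st.floats(20.0, 90.0))
def test_closed_forms_against_raw_arithmetic(ref, comp, se_r, se_c, mu_est):
    """Each measure reduces to its closed form recomputed from raw inputs."""
    a, b = _sub("ref", ref, se=se_r), _sub("comp", comp, se=se_c)
    mu = NationalAverage(estimate=mu_est, se=0.8, population=2000)
    d = difference(a, b)
    assert d.estimate == ref - comp
    assert -100.0 <= d.estimate <= 100.0
    assert d.ui_upper - d.estimate == pytest.approx(
        1.96 * math.sqrt(se_r**2 + se_c**2), rel=1e-12)
    r = ratio(a, b)
    assert r.estimate == ref / comp > 0
    assert math.log(r.ui_upper / r.estimate) == pytest.approx(
        1.96 * math.hypot(se_r / ref, se_c / comp), rel=1e-9)
    pr = par(a, mu, peers=[a, b])
    assert pr.estimate == max(ref - mu_est, 0.0)
    f = paf(pr, mu)
    assert f.estimate == pytest.approx(100.0 * pr.estimate / mu_est, abs=1e-12)


@given(mu_est=st.floats(30.0, 90.0), ref=st.floats(40.0, 99.0))
def test_paf_par_scale_coupling_exact(mu_est, ref):
    """PAF = 100 PAR / mu with bounds scaled identically, bit for bit."""
    a = _sub("ref", ref, se=1.3)
    mu = NationalAverage(estimate=mu_est, se=0.7, population=5000)
    pr = par(a, mu, peers=[a])
    f = paf(pr, mu)
    scale = 100.0 / mu_est
    assert f.ui_lower == pr.ui_lower * scale
    assert f.ui_upper == pr.ui_upper * scale
    if not pr.truncated:
        assert f.estimate == pr.estimate * scale
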