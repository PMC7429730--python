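"""Survey-weighted estimation: point estimates, variances, intervals."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from _oracles import brute_force_prevalence

from anc_equity import (
    DimensionSpec,
    SyntheticConfig,
    estimate_interval,
    generate_survey,
    national_average,
    study_dimensions,
    summaries_from_published,
    truth_summary,
    weighted_prevalence,
)
from anc_equity.synthetic import OutcomeModel

RES = DimensionSpec("residence", ("Rural", "Urban"), "binary", advantaged_end="Urban")


def _small_config(n_clusters: int, seed: int, **model_kw) -> SyntheticConfig:
    regions = ("Alfa", "Bravo")
    return SyntheticConfig(
        regions=regions,
        region_population_share={"Alfa": 0.6, "Bravo": 0.4},
        urban_share_by_region={"Alfa": 0.7, "Bravo": 0.4},
        n_clusters_per_stratum=n_clusters,
        n_women_per_cluster=20,
        outcome_model=OutcomeModel(region_effects={"Alfa": 0.3, "Bravo": -0.2},
                                   **model_kw),
        seed=seed,
    )


def test_hand_computed_weighted_prevalence(tiny_records):
    [est] = weighted_prevalence(tiny_records, RES, suppress_below=0)
    # (2*1 + 1*0 + 1*1) / 4 = 0.75
    assert est.estimate == pytest.approx(75.0)
    assert est.subgroup == "Rural"
    assert est.n_unweighted == 3


def test_equal_weights_reduce_to_unweighted_proportion():
    rng = np.random.default_rng(1)
    n = 200
    df = pd.DataFrame({
        "anc4": rng.integers(0, 2, n),
        "weight": np.full(n, 3.7),
        "stratum_id": "s",
        "cluster_id": rng.integers(0, 8, n),
        "residence": rng.choice(["Rural", "Urban"], n),
    })
    for est in weighted_prevalence(df, RES, suppress_below=0):
        grp = df[df["residence"] == est.subgroup]
        assert est.estimate == pytest.approx(100.0 * grp["anc4"].mean(), abs=1e-12)


def test_grouped_matches_brute_force_exactly():
    rng = np.random.default_rng(99)
    for _ in range(20):
        n = int(rng.integers(5, 300))
        df = pd.DataFrame({
            "anc4": rng.integers(0, 2, n),
            "weight": rng.uniform(0.1, 5.0, n),
            "stratum_id": rng.choice(["a", "b", "c"], n),
            "cluster_id": rng.integers(0, 4, n),
            "residence": rng.choice(["Rural", "Urban"], n),
        })
        oracle = brute_force_prevalence(df, "residence")
        for est in weighted_prevalence(df, RES, suppress_below=0):
            assert est.estimate == oracle[est.subgroup]  # bitwise


def test_population_weighted_conservation(default_survey, dims):
    # share-weighted subgroup estimates aggregate exactly to mu
    records, _ = default_survey
    mu = national_average(records, population="weighted")
    for dim in dims.values():
        ests = weighted_prevalence(records, dim, population="weighted",
                                   suppress_below=0)
        total = sum(e.population for e in ests)
        agg = sum(e.population * e.estimate for e in ests) / total
        assert agg == pytest.approx(mu.estimate, abs=1e-9)
        assert min(e.estimate for e in ests) <= mu.estimate <= max(
            e.estimate for e in ests)


def test_synthetic_estimates_recover_truth(large_survey, dims):
    records, truth = large_survey
    assert len(records) > 19000
    for name, dim in dims.items():
        tr = dict(truth_summary(truth, dim))
        for est in weighted_prevalence(records, dim, suppress_below=0):
            assert abs(est.estimate - tr[est.subgroup]) < 1.5 + 3.0 * est.se
    mu = national_average(records)
    assert abs(mu.estimate - truth.national_average) < 1.0


def test_clustered_se_exceeds_iid_se():
    # strong cluster-level random effects: linearized SE must see them
    records, _ = generate_survey(_small_config(30, seed=5, cluster_sd=1.0))
    mu_clustered = national_average(records)
    iid = records.copy()
    iid["cluster_id"] = np.arange(len(iid))  # every woman her own PSU
    mu_iid = national_average(iid)
    assert mu_clustered.se > mu_iid.se
    se_c = {e.subgroup: e.se for e in weighted_prevalence(records, RES)}
    se_i = {e.subgroup: e.se for e in weighted_prevalence(iid, RES)}
    assert all(se_c[g] > se_i[g] for g in se_c)


def test_se_shrinks_with_sample_size():
    sizes = (5, 15, 45)
    mean_se = []
    for n_clusters in sizes:
        ses = [national_average(generate_survey(
            _small_config(n_clusters, seed=s))[0]).se for s in range(10)]
        mean_se.append(np.mean(ses))
    assert mean_se[0] > mean_se[1] > mean_se[2]


def test_logit_wald_interval_closed_form():
    lo, hi = estimate_interval(50.0, 5.0)
    assert (round(lo, 2), round(hi, 2)) == (40.32, 59.68)
    # asymmetry: upper half-width shrinks near 100
    lo, hi = estimate_interval(90.0, 3.0)
    assert hi - 90.0 < 90.0 - lo
    assert estimate_interval(37.5, 0.0) == (37.5, 37.5)


def test_boundary_estimate_falls_back_to_wilson():
    lo, hi = estimate_interval(0.0, 0.0, n_eff=50)
    assert lo == 0.0 and 0.0 < hi < 15.0
    with pytest.raises(ValueError, match="effective sample size"):
        estimate_interval(100.0, 0.0)
    df = pd.DataFrame({
        "anc4": [0] * 40, "weight": 1.0, "stratum_id": "s",
        "cluster_id": [0] * 20 + [1] * 20, "residence": ["Rural"] * 40,
    })
    [est] = weighted_prevalence(df, RES, suppress_below=0)
    assert est.ci_method == "wilson"
    assert est.estimate == 0.0 and est.ci_upper > 0.0


def test_small_subgroups_flagged_not_dropped():
    df = pd.DataFrame({
        "anc4": [1, 0] * 15 + [1],
        "weight": 1.0, "stratum_id": "s",
        "cluster_id": list(range(31)),
        "residence": ["Rural"] * 30 + ["Urban"],
    })
    ests = weighted_prevalence(df, RES, suppress_below=25)
    flags = {e.subgroup: e.suppressed for e in ests}
    assert flags == {"Rural": False, "Urban": True}


def test_published_se_back_derivation():
    rows = pd.DataFrame({
        "dimension": ["economic_status"] * 2,
        "subgroup": ["Quintile 1 (poorest)", "Quintile 5 (richest)"],
        "estimate": [34.03, 88.18],
        "ci_lower": [30.44, 85.23],
        "ci_upper": [37.82, 90.61],
        "population": [1674, 1422],
    })
    poor, rich = summaries_from_published(rows)
    assert poor.se == pytest.approx((37.82 - 30.44) / 3.92, abs=1e-12)
    assert round(poor.se, 3) == 1.883
    assert round(rich.se, 3) == 1.372
    assert (poor.ci_lower, poor.ci_upper) == (30.44, 37.82)  # verbatim


def test_published_roundtrip_symmetric_interval():
    p, s = 62.0, 2.4
    rows = pd.DataFrame({
        "dimension": ["d"], "subgroup": ["g"], "estimate": [p],
        "ci_lower": [p - 1.96 * s], "ci_upper": [p + 1.96 * s],
        "population": [100],
    })
    [est] = summaries_from_published(rows)
    assert est.se == pytest.approx(s, abs=1e-12)


def test_malformed_published_interval_names_subgroup():
    rows = pd.DataFrame({
        "dimension": ["d"], "subgroup": ["Quintile 9"], "estimate": [50.0],
        "ci_lower": [51.0], "ci_upper": [60.0], "population": [10],
    })
    with pytest.raises(ValueError, match="Quintile 9"):
        summaries_from_published(rows)


def test_national_average_single_subgroup_identity(tiny_records):
    [est] = weighted_prevalence(tiny_records, RES, suppress_below=0)
    mu = national_average(tiny_records)
    assert mu.estimate == est.estimate
    assert mu.se == est.se


def test_residence_rows_aggregate_to_printed_national(table1):
    # population-weighted mean of the two published residence rows sits
    # within 0.05 of the published national average
    grouped, mu = table1
    res = grouped["residence"]
    agg = (sum(e.estimate * e.population for e in res)
           / sum(e.population for e in res))
    assert abs(agg - mu.estimate) < 0.05
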