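"""DHS-like synthetic survey generator with known truth.

The real analysis data — unit records from the 2015-16 Angola survey — are
access-restricted, so estimation and measure code is validated against a
simulated stratified two-stage cluster sample whose true coverage surface is
known exactly.  The emulation target is the analysis denominator of that
survey: roughly 8,500 women with a recent live birth spread over 18 regions
crossed with urban/rural residence (36 design strata), with wealth and
education composition skewed richer/more educated in urban strata so the
stratifiers are correlated as in real DHS data.

Outcome model: each woman's probability of attaining ANC4+ follows a
logistic model with additive log-odds effects for wealth quintile,
education, residence and region, plus a normal cluster-level random effect
(sd ``cluster_sd``) shared by the women of one sampled cluster.  The *truth*
for a covariate cell is the marginal probability E[expit(eta + sigma*U)],
computed by Gauss-Hermite quadrature, so that truth and data-generating
process agree exactly even with cluster heterogeneity.

Design weights: every stratum receives the same number of clusters and
women (small regions are oversampled, as DHS designs do), so the base
weight is the stratum population share divided by its sample share;
lognormal noise with mean 1 and configurable sigma reproduces the spread of
real DHS weights without modelling the full two-phase frame.

Randomness: a single integer seed drives one ``numpy`` Generator, consumed
in a fixed, documented order — (1) cluster effects, (2) wealth uniforms,
(3) education uniforms, (4) outcome uniforms, (5) weight-noise normals —
each as one vectorized draw over records sorted stratum-major, then
cluster-major.  The same config and seed therefore reproduce the record
stream byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .dimensions import (
    ANGOLA_REGIONS,
    EDUCATION_CATEGORIES,
    RESIDENCE_CATEGORIES,
    WEALTH_CATEGORIES,
    DimensionSpec,
)


class ConfigError(ValueError):
    """Invalid synthetic-survey configuration."""


#: Region population shares emulating the relative sizes of the 2015-16
#: Angola analysis sample (Luanda dominant, several small interior regions).
DEFAULT_REGION_SHARES = {
    "Cabinda": 191, "Zaire": 186, "Uige": 460, "Luanda": 2696,
    "Cuanza Norte": 111, "Cuanza Sul": 676, "Malanje": 323,
    "Lunda Norte": 247, "Benguela": 754, "Huambo": 650, "Bie": 414,
    "Moxico": 167, "Cuando Cubango": 164, "Namibe": 108, "Huila": 763,
    "Cunene": 321, "Lunda Sul": 163, "Bengo": 92,
}

DEFAULT_URBAN_SHARE = {
    "Cabinda": 0.70, "Zaire": 0.55, "Uige": 0.40, "Luanda": 0.95,
    "Cuanza Norte": 0.45, "Cuanza Sul": 0.35, "Malanje": 0.45,
    "Lunda Norte": 0.50, "Benguela": 0.60, "Huambo": 0.50, "Bie": 0.35,
    "Moxico": 0.45, "Cuando Cubango": 0.45, "Namibe": 0.65, "Huila": 0.40,
    "Cunene": 0.35, "Lunda Sul": 0.55, "Bengo": 0.50,
}

#: Regional log-odds offsets loosely tracking the observed coverage gradient
#: (Luanda/Zaire high, Cuanza Sul/Moxico/Lunda Norte low).
DEFAULT_REGION_EFFECTS = {
    "Cabinda": 0.45, "Zaire": 1.30, "Uige": -0.45, "Luanda": 1.10,
    "Cuanza Norte": 0.15, "Cuanza Sul": -0.75, "Malanje": 0.15,
    "Lunda Norte": -0.50, "Benguela": 0.30, "Huambo": 0.50, "Bie": 0.00,
    "Moxico": -0.50, "Cuando Cubango": -0.30, "Namibe": 0.60,
    "Huila": -0.05, "Cunene": 0.55, "Lunda Sul": 0.45, "Bengo": 0.50,
}


@dataclass(frozen=True)
class OutcomeModel:
    """Additive logistic model for the ANC4+ probability.

    Effects are log-odds offsets relative to the first category of each
    stratifier; `cluster_sd` is the standard deviation of the normal
    cluster-level random intercept.
    """

    intercept: float = -2.0
    wealth_effects: tuple[float, ...] = (0.0, 0.45, 1.0, 1.7, 2.2)
    education_effects: tuple[float, ...] = (0.0, 0.55, 1.1)
    residence_effects: tuple[float, ...] = (0.0, 0.65)   # (rural, urban)
    region_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_EFFECTS))
    cluster_sd: float = 0.25

    def __post_init__(self) -> None:
        if len(self.wealth_effects) != 5:
            raise ConfigError("wealth_effects must have 5 levels")
        if len(self.education_effects) != 3:
            raise ConfigError("education_effects must have 3 levels")
        if len(self.residence_effects) != 2:
            raise ConfigError("residence_effects must have 2 levels (rural, urban)")
        if self.cluster_sd < 0:
            raise ConfigError("cluster_sd must be nonnegative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and outcome configuration for one synthetic survey.

    Defaults emulate the Angola study conditions: 18 regions x urban/rural
    (36 strata), 14 clusters of 17 women each per stratum (8,568 women),
    urban strata skewed rich/educated, modest weight dispersion and cluster
    heterogeneity.
    """

    regions: tuple[str, ...] = tuple(ANGOLA_REGIONS)
    region_population_share: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SHARES))
    urban_share_by_region: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_URBAN_SHARE))
    n_clusters_per_stratum: int = 14
    n_women_per_cluster: int = 17
    # category probabilities by residence (rural row, urban row)
    wealth_probs: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.38, 0.30, 0.18, 0.10, 0.04),
        (0.08, 0.15, 0.22, 0.27, 0.28),
    )
    education_probs: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.45, 0.40, 0.15),
        (0.15, 0.38, 0.47),
    )
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    weight_dispersion: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.regions) < 1:
            raise ConfigError("need at least one region")
        if self.n_clusters_per_stratum < 2:
            first = f"{self.regions[0]}/{RESIDENCE_CATEGORIES[0]}"
            raise ConfigError(
                f"stratum {first!r} has {self.n_clusters_per_stratum} cluster(s); "
                "variance estimation needs >=2 clusters per stratum"
            )
        if self.n_women_per_cluster < 1:
            raise ConfigError("n_women_per_cluster must be positive")
        if self.weight_dispersion < 0:
            raise ConfigError("weight_dispersion must be nonnegative")
        for r in self.regions:
            if r not in self.region_population_share:
                raise ConfigError(f"no population share for region {r!r}")
            if r not in self.urban_share_by_region:
                raise ConfigError(f"no urban share for region {r!r}")
            if not 0.0 < self.urban_share_by_region[r] < 1.0:
                raise ConfigError(f"urban share for region {r!r} must be in (0, 1)")
            if self.region_population_share[r] <= 0:
                raise ConfigError(f"population share for region {r!r} must be positive")
            if r not in self.outcome_model.region_effects:
                raise ConfigError(f"no region effect for region {r!r}")
        for probs, k in ((self.wealth_probs, 5), (self.education_probs, 3)):
            for row in probs:
                if len(row) != k or abs(sum(row) - 1.0) > 1e-9 or min(row) <= 0:
                    raise ConfigError(
                        "category probabilities must be positive and sum to 1"
                    )

    @property
    def n_women(self) -> int:
        return (len(self.regions) * len(RESIDENCE_CATEGORIES)
                * self.n_clusters_per_stratum * self.n_women_per_cluster)


@dataclass
class SyntheticTruth:
    """Exact coverage surface of a synthetic survey.

    `cells` has one row per region x residence x wealth x education cell
    with its marginal outcome probability and population share; every
    estimand (subgroup coverage, national average) is a share-weighted mean
    over cells, so the arithmetic identities between them hold exactly.
    """

    cells: pd.DataFrame  # region, residence, wealth_quintile, education, probability, share

    def __post_init__(self) -> None:
        s = self.cells["share"].to_numpy()
        p = self.cells["probability"].to_numpy()
        if abs(s.sum() - 1.0) > 1e-9:
            raise ValueError("cell population shares must sum to 1")
        if not ((p > 0) & (p < 1)).all():
            raise ValueError("cell probabilities must lie strictly in (0, 1)")

    @property
    def national_average(self) -> float:
        """True national coverage, in %."""
        return 100.0 * float(
            (self.cells["share"] * self.cells["probability"]).sum())

    def subgroup_coverage(self, column: str) -> pd.Series:
        """True coverage (%) per subgroup of the cell column `column`."""
        if column not in self.cells.columns:
            raise KeyError(f"unknown stratifier column {column!r}")
        g = self.cells.groupby(column, sort=False)
        return 100.0 * g.apply(
            lambda c: (c["share"] * c["probability"]).sum() / c["share"].sum(),
            include_groups=False,
        )


def truth_summary(
    truth: SyntheticTruth, dimension: DimensionSpec
) -> list[tuple[str, float]]:
    """(subgroup, true coverage %) pairs for one dimension, in category order."""
    cov = truth.subgroup_coverage(dimension.colname)
    missing = [c for c in dimension.categories if c not in cov.index]
    if missing:
        raise KeyError(
            f"dimension {dimension.name!r} categories {missing} absent from truth table"
        )
    return [(c, float(cov[c])) for c in dimension.categories]


def _gauss_hermite_probability(eta: np.ndarray, sd: float, order: int = 40) -> np.ndarray:
    """Marginal P(Y=1) = E[expit(eta + sd*U)], U ~ N(0,1), by quadrature."""
    if sd == 0.0:
        return expit(eta)
    nodes, weights = np.polynomial.hermite.hermgauss(order)
    # E[f(eta + sd U)] = sum_k w_k/sqrt(pi) * f(eta + sd*sqrt(2)*x_k)
    vals = expit(eta[..., None] + sd * np.sqrt(2.0) * nodes)
    return vals @ (weights / np.sqrt(np.pi))


def _truth_table(config: SyntheticConfig) -> SyntheticTruth:
    m = config.outcome_model
    rows = []
    total = sum(config.region_population_share[r] for r in config.regions)
    for r in config.regions:
        rshare = config.region_population_share[r] / total
        ushare = config.urban_share_by_region[r]
        for res_i, res in enumerate(RESIDENCE_CATEGORIES):  # (Rural, Urban)
            res_share = ushare if res == "Urban" else 1.0 - ushare
            for w_i, wcat in enumerate(WEALTH_CATEGORIES):
                for e_i, ecat in enumerate(EDUCATION_CATEGORIES):
                    eta = (m.intercept + m.wealth_effects[w_i]
                           + m.education_effects[e_i]
                           + m.residence_effects[res_i]
                           + m.region_effects[r])
                    share = (rshare * res_share
                             * config.wealth_probs[res_i][w_i]
                             * config.education_probs[res_i][e_i])
                    rows.append((r, res, wcat, ecat, eta, share))
    cells = pd.DataFrame(
        rows, columns=["region", "residence", "wealth_quintile", "education",
                       "eta", "share"])
    cells["probability"] = _gauss_hermite_probability(
        cells.pop("eta").to_numpy(), m.cluster_sd)
    return SyntheticTruth(cells=cells[
        ["region", "residence", "wealth_quintile", "education",
         "probability", "share"]])


def generate_survey(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic survey and return (records, truth).

    Records carry the unit-level schema: woman_id, region, residence,
    wealth_quintile, education, anc4, weight, stratum_id, cluster_id.
    Identical config and seed reproduce the frame exactly.
    """
    truth = _truth_table(config)
    m = config.outcome_model
    rng = np.random.default_rng(config.seed)

    n_res = len(RESIDENCE_CATEGORIES)
    n_strata = len(config.regions) * n_res
    cpq, wpc = config.n_clusters_per_stratum, config.n_women_per_cluster
    n = n_strata * cpq * wpc

    # per-record design indices, stratum-major then cluster-major
    strat = np.repeat(np.arange(n_strata), cpq * wpc)
    clus_in_strat = np.tile(np.repeat(np.arange(cpq), wpc), n_strata)
    region_i = strat // n_res
    res_i = strat % n_res

    # draw order is part of the reproducibility contract (see module docstring)
    cluster_eff = rng.normal(0.0, m.cluster_sd, size=n_strata * cpq)
    u_wealth = rng.random(n)
    u_educ = rng.random(n)
    u_outcome = rng.random(n)
    log_noise = rng.normal(0.0, 1.0, size=n)

    wealth_cum = np.cumsum(np.asarray(config.wealth_probs, dtype=float), axis=1)
    educ_cum = np.cumsum(np.asarray(config.education_probs, dtype=float), axis=1)
    wealth_i = np.empty(n, dtype=np.int64)
    educ_i = np.empty(n, dtype=np.int64)
    for ri in range(n_res):
        mask = res_i == ri
        wealth_i[mask] = np.searchsorted(wealth_cum[ri], u_wealth[mask], side="right")
        educ_i[mask] = np.searchsorted(educ_cum[ri], u_educ[mask], side="right")
    wealth_i = np.minimum(wealth_i, 4)
    educ_i = np.minimum(educ_i, 2)

    region_eff = np.array([m.region_effects[r] for r in config.regions])
    eta = (m.intercept
           + np.asarray(m.wealth_effects)[wealth_i]
           + np.asarray(m.education_effects)[educ_i]
           + np.asarray(m.residence_effects)[res_i]
           + region_eff[region_i]
           + cluster_eff[strat * cpq + clus_in_strat])
    anc4 = (u_outcome < expit(eta)).astype(np.int64)

    # base weight: stratum population share / stratum sample share
    total = sum(config.region_population_share[r] for r in config.regions)
    strat_pop = np.empty(n_strata)
    for ri, r in enumerate(config.regions):
        ush = config.urban_share_by_region[r]
        rsh = config.region_population_share[r] / total
        strat_pop[ri * n_res + 0] = rsh * (1.0 - ush)   # rural
        strat_pop[ri * n_res + 1] = rsh * ush           # urban
    sample_share = (cpq * wpc) / n
    base_w = strat_pop / sample_share
    sigma = config.weight_dispersion
    weight = base_w[strat] * np.exp(-0.5 * sigma**2 + sigma * log_noise)

    regions = np.asarray(config.regions)
    residences = np.asarray(RESIDENCE_CATEGORIES)
    records = pd.DataFrame({
        "woman_id": np.arange(1, n + 1),
        "region": regions[region_i],
        "residence": residences[res_i],
        "wealth_quintile": np.asarray(WEALTH_CATEGORIES)[wealth_i],
        "education": np.asarray(EDUCATION_CATEGORIES)[educ_i],
        "anc4": anc4,
        "weight": weight,
        "stratum_id": pd.Series(regions[region_i]).str.cat(
            pd.Series(residences[res_i]), sep="/"),
        "cluster_id": clus_in_strat + 1,
    })
    return records, truth


def write_unit_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write unit-level records in the canonical CSV schema."""
    cols = ["woman_id", "region", "residence", "wealth_quintile", "education",
            "anc4", "weight", "stratum_id", "cluster_id"]
    records[cols].to_csv(path, index=False)


def write_truth_csv(
    truth: SyntheticTruth, dimensions: dict[str, DimensionSpec], path: str | Path
) -> None:
    """Write the true subgroup coverages (dimension, subgroup, true_coverage)."""
    rows = []
    for dim in dimensions.values():
        for sub, cov in truth_summary(truth, dim):
            rows.append((dim.name, sub, cov))
    rows.append(("national_average", "National average", truth.national_average))
    pd.DataFrame(rows, columns=["dimension", "subgroup", "true_coverage"]).to_csv(
        path, index=False)
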