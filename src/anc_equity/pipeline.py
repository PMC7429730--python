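"""End-to-end orchestration: read input, disaggregate, compute all measures.

Two entry levels are supported.  ``unit`` input is a CSV of one row per
woman (outcome, weight, design identifiers, stratifier columns) from which
coverage and its design-based variance are estimated directly; ``subgroup``
input is a CSV of already-published subgroup summaries (estimate, interval,
population) plus one national-average row, from which standard errors are
back-derived.  The published-table route is what makes the benchmark
against the printed Angola tables possible; the unit-level route is what an
analysis of real microdata would use.

Outputs are three tidy tables with fixed column order: the disaggregation
table (one row per subgroup), the measures table (4 measures x dimension)
and a composition table (each subgroup's share of the total population).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dimensions import DimensionSpec, study_dimensions
from .estimation import (
    DEFAULT_SUPPRESS_BELOW,
    NationalAverage,
    SubgroupEstimate,
    national_average,
    summaries_from_published,
    weighted_prevalence,
)
from .fixtures import NATIONAL_DIMENSION, table1_fixture, table2_expected
from .measures import compute_measures

log = logging.getLogger("anc_equity")

UNIT_COLUMNS = ("anc4", "weight", "stratum_id", "cluster_id")

DISAGG_COLUMNS = ["dimension", "subgroup", "estimate", "se", "ci_lower",
                  "ci_upper", "population", "suppressed"]
MEASURE_COLUMNS = ["dimension", "measure", "estimate", "ui_lower", "ui_upper",
                   "reference_subgroup", "comparison_subgroup", "significant"]
COMPOSITION_COLUMNS = ["dimension", "subgroup", "population", "share_percent"]


class SchemaError(ValueError):
    """Input file does not conform to the expected CSV schema."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input: Path | str | None = None
    level: str = "subgroup"                # "unit" | "subgroup"
    dimensions: dict[str, DimensionSpec] = field(default_factory=study_dimensions)
    indicator: str = "anc4"
    confidence: float = 95.0
    reference_overrides: dict[str, tuple[str, str]] = field(default_factory=dict)
    suppress_below: int = DEFAULT_SUPPRESS_BELOW
    population: str = "unweighted"         # reported subgroup counts
    par_method: str = "covariance"
    out_dir: Path | str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in ("unit", "subgroup"):
            raise ValueError("level must be 'unit' or 'subgroup'")
        if not self.dimensions:
            raise ValueError("at least one dimension is required")

    def config_hash(self) -> str:
        payload = {
            "input": str(self.input), "level": self.level,
            "dimensions": sorted(self.dimensions),
            "indicator": self.indicator, "confidence": self.confidence,
            "reference_overrides": {k: list(v) for k, v in self.reference_overrides.items()},
            "suppress_below": self.suppress_below,
            "population": self.population, "par_method": self.par_method,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_unit_records(
    path: Path | str,
    dimensions: dict[str, DimensionSpec] | None = None,
    outcome: str = "anc4",
) -> pd.DataFrame:
    """Read and validate a unit-level survey CSV.

    Raises `SchemaError` naming the missing column, or listing the (1-based
    data) row numbers of non-binary outcomes / non-positive weights.
    """
    dimensions = dimensions if dimensions is not None else study_dimensions()
    df = pd.read_csv(path, float_precision="round_trip")
    required = [outcome, "weight", "stratum_id", "cluster_id"] + [
        d.colname for d in dimensions.values()]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    bad = df.index[~df[outcome].isin([0, 1])] + 1
    if len(bad):
        raise SchemaError(
            f"{path}: non-binary outcome in rows {bad.tolist()[:10]}")
    bad = df.index[~(df["weight"] > 0)] + 1
    if len(bad):
        raise SchemaError(
            f"{path}: non-positive weight in rows {bad.tolist()[:10]}")
    log.info("read %d unit records from %s", len(df), path)
    return df


def read_subgroup_summaries(
    path: Path | str, level: float = 95.0
) -> tuple[dict[str, list[SubgroupEstimate]], NationalAverage]:
    """Read a subgroup-summary CSV into grouped estimates plus mu.

    The file must contain one row with dimension == ``national_average``
    (PAR/PAF cannot be formed without mu) and no duplicated subgroup label
    within a dimension.
    """
    df = pd.read_csv(path)
    required = {"dimension", "subgroup", "estimate", "ci_lower", "ci_upper", "population"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    nat = df[df["dimension"] == NATIONAL_DIMENSION]
    if len(nat) == 0:
        raise SchemaError(
            f"{path}: no national-average row (dimension == {NATIONAL_DIMENSION!r}); "
            "PAR and PAF need mu")
    if len(nat) > 1:
        raise SchemaError(f"{path}: multiple national-average rows")
    sub = df[df["dimension"] != NATIONAL_DIMENSION]
    dup = sub.duplicated(subset=["dimension", "subgroup"])
    if dup.any():
        labels = sub.loc[dup, ["dimension", "subgroup"]].to_records(index=False).tolist()
        raise SchemaError(f"{path}: duplicated subgroup label(s) {labels}")
    try:
        estimates = summaries_from_published(sub, level=level)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    grouped: dict[str, list[SubgroupEstimate]] = {}
    for e in estimates:
        grouped.setdefault(e.dimension, []).append(e)
    row = nat.iloc[0]
    has_ci = pd.notna(row["ci_lower"]) and pd.notna(row["ci_upper"])
    from .estimation import z_value
    mu = NationalAverage(
        estimate=float(row["estimate"]),
        se=(float(row["ci_upper"]) - float(row["ci_lower"])) / (2 * z_value(level))
        if has_ci else None,
        population=float(row["population"]),
        ci_lower=float(row["ci_lower"]) if has_ci else None,
        ci_upper=float(row["ci_upper"]) if has_ci else None,
    )
    log.info("read %d subgroup rows (+mu=%.4f) from %s", len(sub), mu.estimate, path)
    return grouped, mu


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _disaggregation_table(grouped: dict[str, list[SubgroupEstimate]]) -> pd.DataFrame:
    rows = [
        (e.dimension, e.subgroup, e.estimate, e.se, e.ci_lower, e.ci_upper,
         e.population, e.suppressed)
        for dim in grouped.values() for e in dim
    ]
    return pd.DataFrame(rows, columns=DISAGG_COLUMNS)


def _composition_table(grouped: dict[str, list[SubgroupEstimate]]) -> pd.DataFrame:
    rows = []
    for name, ests in grouped.items():
        total = sum(e.population for e in ests)
        for e in ests:
            rows.append((name, e.subgroup, e.population,
                         100.0 * e.population / total if total else float("nan")))
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)


def _measures_table(
    grouped: dict[str, list[SubgroupEstimate]],
    dimensions: dict[str, DimensionSpec],
    mu: NationalAverage,
    config: RunConfig,
) -> pd.DataFrame:
    from .measures import Contrast, select_contrast

    rows = []
    for name, dim in dimensions.items():
        ests = grouped.get(name)
        if not ests:
            continue
        contrast = None
        if name in config.reference_overrides:
            ref_label, comp_label = config.reference_overrides[name]
            by = {e.subgroup: e for e in ests}
            contrast = Contrast(by[ref_label], by[comp_label])
        results = compute_measures(
            ests, dim, mu, level=config.confidence,
            par_method=config.par_method, contrast=contrast)
        for r in results:
            rows.append((r.dimension, r.measure, r.estimate, r.ui_lower,
                         r.ui_upper, r.reference_subgroup,
                         r.comparison_subgroup, r.significant))
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def run_pipeline(
    config: RunConfig,
    records: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run disaggregation + all four measures for every configured dimension.

    Returns (disaggregation, measures, composition) tables; writes them as
    CSV under ``config.out_dir`` when set.  `records` may be passed
    directly to skip re-reading ``config.input``.
    """
    t0 = time.perf_counter()
    stage = "read"
    try:
        if config.level == "unit":
            if records is None:
                if config.input is None:
                    raise SchemaError("unit-level run needs an input path or records")
                records = read_unit_records(
                    config.input, config.dimensions, outcome=config.indicator)
            stage = "estimate"
            grouped = {
                name: weighted_prevalence(
                    records, dim, outcome=config.indicator,
                    level=config.confidence,
                    suppress_below=config.suppress_below,
                    population=config.population)
                for name, dim in config.dimensions.items()
            }
            mu = national_average(
                records, outcome=config.indicator, level=config.confidence,
                population=config.population)
        else:
            if config.input is None:
                raise SchemaError("subgroup-level run needs an input path")
            grouped, mu = read_subgroup_summaries(config.input, level=config.confidence)
        stage = "measures"
        measures = _measures_table(grouped, config.dimensions, mu, config)
        disagg = _disaggregation_table(grouped)
        composition = _composition_table(grouped)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    for _, row in disagg[disagg["suppressed"]].iterrows():
        log.warning("suppressed subgroup %s/%s (n below threshold)",
                    row["dimension"], row["subgroup"])
    log.info("pipeline run %s finished in %.3fs (%d subgroups, %d measures)",
             config.config_hash(), time.perf_counter() - t0, len(disagg), len(measures))

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        disagg.to_csv(out / "disaggregation.csv", index=False)
        measures.to_csv(out / "measures.csv", index=False)
        composition.to_csv(out / "composition.csv", index=False)
    return disagg, measures, composition


# ---------------------------------------------------------------------------
# benchmark against the published tables
# ---------------------------------------------------------------------------

BENCHMARK_TOLERANCE = 0.02  # pp (D/PAR/PAF) or ratio units (R)


def reproduce_paper_benchmark(
    tolerance: float = BENCHMARK_TOLERANCE,
    subgroup_csv: Path | str | None = None,
) -> pd.DataFrame:
    """Recompute all 16 summary measures from the packaged subgroup table
    and diff them against the packaged published-measure table.

    Returns a report with one row per (dimension, measure): computed value,
    published value, absolute difference and a within-tolerance flag.
    `subgroup_csv` substitutes an alternative subgroup table (same schema)
    for sensitivity checks.
    """
    if subgroup_csv is not None:
        grouped, mu = read_subgroup_summaries(subgroup_csv)
    else:
        grouped, mu = table1_fixture()
    dims = study_dimensions()
    cfg = RunConfig(level="subgroup", dimensions=dims)
    measures = _measures_table(grouped, dims, mu, cfg)
    expected = table2_expected()
    merged = expected.merge(
        measures[["dimension", "measure", "estimate"]],
        on=["dimension", "measure"], suffixes=("_published", "_computed"),
        validate="one_to_one",
    )
    report = pd.DataFrame({
        "dimension": merged["dimension"],
        "measure": merged["measure"],
        "computed": merged["estimate_computed"],
        "published": merged["estimate_published"],
        "abs_diff": (merged["estimate_computed"] - merged["estimate_published"]).abs(),
    })
    report["within_tolerance"] = report["abs_diff"] <= tolerance
    return report
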