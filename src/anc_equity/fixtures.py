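"""Packaged benchmark tables from the 2015-16 Angola ANC4+ analysis.

Two small CSVs ship with the package: the published subgroup coverage table
(28 subgroup rows across the four stratifiers plus the national-average
row, values exactly as printed) and the published summary-measure table
(4 dimensions x 4 measures with 95% uncertainty intervals).  Together they
let the whole measures pipeline run — and be benchmarked — without the
access-restricted survey microdata.
"""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path

import pandas as pd

from .estimation import NationalAverage, SubgroupEstimate, summaries_from_published

SUBGROUP_TABLE = "angola2015_anc4_subgroups.csv"
MEASURES_TABLE = "angola2015_anc4_measures.csv"

NATIONAL_DIMENSION = "national_average"


def _data(name: str) -> pd.DataFrame:
    with as_file(files("anc_equity").joinpath("data", name)) as p:
        return pd.read_csv(p)


def table1_path() -> Path:
    """Filesystem path of the packaged subgroup-coverage CSV."""
    with as_file(files("anc_equity").joinpath("data", SUBGROUP_TABLE)) as p:
        return Path(p)


def table1_fixture() -> tuple[dict[str, list[SubgroupEstimate]], NationalAverage]:
    """Published subgroup estimates grouped by dimension, plus mu.

    Standard errors are back-derived from the printed intervals as
    (upper - lower)/3.92; the national average (printed without an
    interval) carries ``se=None``, so measures that need Var(mu)
    reconstruct it from the subgroup rows.
    """
    df = _data(SUBGROUP_TABLE)
    nat = df[df["dimension"] == NATIONAL_DIMENSION]
    if len(nat) != 1:
        raise ValueError("fixture must contain exactly one national-average row")
    sub = df[df["dimension"] != NATIONAL_DIMENSION]
    estimates = summaries_from_published(sub)
    grouped: dict[str, list[SubgroupEstimate]] = {}
    for e in estimates:
        grouped.setdefault(e.dimension, []).append(e)
    row = nat.iloc[0]
    mu = NationalAverage(
        estimate=float(row["estimate"]), se=None,  # type: ignore[arg-type]
        population=float(row["population"]),
    )
    return grouped, mu


def table2_expected() -> pd.DataFrame:
    """Published summary-measure table (dimension, measure, estimate, UI)."""
    return _data(MEASURES_TABLE)
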