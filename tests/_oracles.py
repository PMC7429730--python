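"""Independent brute-force oracles used by several test modules."""

from __future__ import annotations

import pandas as pd


def brute_force_prevalence(
    records: pd.DataFrame,
    group_col: str,
    outcome: str = "anc4",
    weight: str = "weight",
) -> dict[str, float]:
    """Per-record accumulation of 100 * sum(w*y)/sum(w) per subgroup.

    Deliberately naive: a Python loop in record order, no vectorisation,
    so it shares nothing with the grouped implementation it checks.
    """
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for _, row in records.iterrows():
        g = row[group_col]
        num[g] = num.get(g, 0.0) + row[weight] * row[outcome]
        den[g] = den.get(g, 0.0) + row[weight]
    return {g: 100.0 * (num[g] / den[g]) for g in num}
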