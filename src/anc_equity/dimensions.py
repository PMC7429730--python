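"""Equity stratifiers (inequality dimensions) and their ordering semantics.

A dimension partitions the surveyed population into subgroups.  Whether the
categories carry an a-priori advantage ranking decides how the reference and
comparison subgroups for the summary measures are chosen: for ordered or
binary dimensions (wealth quintile, education, residence) the advantaged end
is fixed in advance; for non-ordered dimensions (subnational region) the
best- and worst-performing subgroups are identified from the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

Semantics = Literal["ordered", "binary", "non_ordered"]

#: Subnational regions of Angola in the order the 2015-16 survey reports them.
ANGOLA_REGIONS = [
    "Cabinda", "Zaire", "Uige", "Luanda", "Cuanza Norte", "Cuanza Sul",
    "Malanje", "Lunda Norte", "Benguela", "Huambo", "Bie", "Moxico",
    "Cuando Cubango", "Namibe", "Huila", "Cunene", "Lunda Sul", "Bengo",
]

WEALTH_CATEGORIES = [
    "Quintile 1 (poorest)", "Quintile 2", "Quintile 3", "Quintile 4",
    "Quintile 5 (richest)",
]
EDUCATION_CATEGORIES = ["No education", "Primary school", "Secondary school +"]
RESIDENCE_CATEGORIES = ["Rural", "Urban"]


@dataclass(frozen=True)
class DimensionSpec:
    """One equity stratifier: its categories and reference-group rule.

    Parameters
    ----------
    name:
        Dimension label, e.g. ``"economic_status"``.
    categories:
        Ordered category labels.  For ``ordered``/``binary`` semantics the
        list runs from the least to the most advantaged category (or the
        reverse; ``advantaged_end`` names the advantaged one explicitly).
    semantics:
        ``"ordered"`` (inherent ranking, >2 levels), ``"binary"`` or
        ``"non_ordered"`` (no inherent ranking; region).
    advantaged_end:
        The a-priori most advantaged category.  Required unless
        ``semantics == "non_ordered"``, in which case it must be ``None``.
    column:
        Column name carrying this dimension in unit-level record tables.
        Defaults to ``name``.
    """

    name: str
    categories: tuple[str, ...]
    semantics: Semantics
    advantaged_end: str | None = None
    column: str | None = None

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError(f"dimension {self.name!r} needs >=2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"dimension {self.name!r} has duplicate categories")
        if self.semantics == "non_ordered":
            if self.advantaged_end is not None:
                raise ValueError(
                    f"non-ordered dimension {self.name!r} cannot fix an advantaged end"
                )
        else:
            if self.advantaged_end is None:
                raise ValueError(
                    f"{self.semantics} dimension {self.name!r} must name advantaged_end"
                )
            if self.advantaged_end not in self.categories:
                raise ValueError(
                    f"advantaged_end {self.advantaged_end!r} not a category of {self.name!r}"
                )

    @property
    def colname(self) -> str:
        return self.column if self.column is not None else self.name

    @property
    def disadvantaged_end(self) -> str | None:
        """Category at the opposite extreme from ``advantaged_end`` (ordered/binary)."""
        if self.advantaged_end is None:
            return None
        if self.categories[0] == self.advantaged_end:
            return self.categories[-1]
        return self.categories[0]


def study_dimensions(regions: list[str] | None = None) -> dict[str, DimensionSpec]:
    """The four stratifiers used in the Angola ANC analysis.

    Wealth and education are ordered with the richest / most educated end
    advantaged, residence is binary with urban advantaged, and region is
    non-ordered (the reference is whichever region performs best).
    """
    regions = list(ANGOLA_REGIONS) if regions is None else list(regions)
    return {
        "economic_status": DimensionSpec(
            "economic_status", tuple(WEALTH_CATEGORIES), "ordered",
            advantaged_end=WEALTH_CATEGORIES[-1], column="wealth_quintile",
        ),
        "education": DimensionSpec(
            "education", tuple(EDUCATION_CATEGORIES), "ordered",
            advantaged_end=EDUCATION_CATEGORIES[-1],
        ),
        "residence": DimensionSpec(
            "residence", tuple(RESIDENCE_CATEGORIES), "binary",
            advantaged_end="Urban",
        ),
        "region": DimensionSpec("region", tuple(regions), "non_ordered"),
    }
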