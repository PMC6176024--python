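"""Condition filtering and category stratification.

Exposure durations beyond 24 h mix stress responses and blur the initial
mechanism of toxicity, so the standard analysis drops every condition
measured after 24 h (the 24 h time point itself is retained).  Early
in-vivo kidney time points (3 and 6 h) are deliberately kept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import CategoryKey, ConfigError, FoldChangeMatrix, normalize_chemical

__all__ = ["SelectionReport", "filter_by_max_time", "select_category", "select_chemical_conditions"]


@dataclass(frozen=True)
class SelectionReport:
    """Before/after accounting for one filtering step."""

    n_conditions_before: int
    n_conditions_after: int
    n_values_before: int
    n_values_after: int
    description: str

    def __post_init__(self) -> None:
        assert self.n_conditions_after <= self.n_conditions_before
        assert self.n_values_after <= self.n_values_before


def filter_by_max_time(
    matrix: FoldChangeMatrix, max_hours: float = 24.0
) -> tuple[FoldChangeMatrix, SelectionReport]:
    """Keep conditions with exposure time <= *max_hours* (inclusive).

    ``max_hours=math.inf`` disables the filter.  "After 24 h" is read as
    strictly greater than 24 h, so the 24 h time point survives the
    default cut.
    """
    if not max_hours > 0:
        raise ConfigError(f"max_hours must be > 0, got {max_hours}")
    keep = matrix.conditions.index[matrix.conditions["time_h"] <= max_hours]
    out = matrix.subset_conditions(keep)
    report = SelectionReport(
        n_conditions_before=matrix.n_conditions,
        n_conditions_after=out.n_conditions,
        n_values_before=matrix.n_values,
        n_values_after=out.n_values,
        description=(
            "no time filter" if math.isinf(max_hours) else f"time_h <= {max_hours:g} h"
        ),
    )
    return out, report


def select_category(matrix: FoldChangeMatrix, key: CategoryKey) -> FoldChangeMatrix:
    """Keep conditions matching every non-wildcard field of *key*."""
    mask = matrix.conditions.apply(key.matches, axis=1) if matrix.n_conditions else []
    keep = matrix.conditions.index[mask] if matrix.n_conditions else []
    out = matrix.subset_conditions(keep)
    if out.n_conditions == 0:
        warnings.warn(f"category {key.label()} selects no conditions", stacklevel=2)
    return out


def select_chemical_conditions(
    matrix: FoldChangeMatrix, chemicals: Sequence[str]
) -> FoldChangeMatrix:
    """Keep conditions of any chemical in *chemicals* (case-insensitive).

    Emits an "uncovered activator" warning naming every requested chemical
    with no condition in the dataset; an entirely uncovered request yields
    an empty matrix rather than an error, so stratified analyses can
    record the gap and continue.
    """
    if not chemicals:
        raise ConfigError("chemical list must be non-empty")
    wanted = {normalize_chemical(c): c for c in chemicals}
    chem_norm = matrix.conditions["chemical"].map(normalize_chemical)
    keep = matrix.conditions.index[chem_norm.isin(wanted)]
    present = set(chem_norm)
    uncovered = [orig for norm, orig in wanted.items() if norm not in present]
    if uncovered:
        warnings.warn(
            "uncovered activator chemical(s): " + ", ".join(sorted(uncovered)),
            stacklevel=2,
        )
    return matrix.subset_conditions(keep)
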