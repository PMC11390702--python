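"""Temporal domain boundaries from cumulative flowering records.

The flowering season (the domain) for a region is set by a quantile rule on
the cumulative distribution of flowering records over the calendar year: the
start is the earliest month whose cumulative fraction exceeds ``q_low`` and
the end is the earliest month whose cumulative fraction reaches ``q_high``.
The default tails are 5%/95% (the stricter rule); 2.5%/97.5% is the
sensitivity alternative. A "record" is one (species, flowering month) pair by
default; a species-midpoint reading is available behind a switch. The legacy
whole-season rule (min first month to max last month) is rule ``"minmax"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .flora import FloweringRecord, TemporalDomain, to_range

RECORD_DEFINITIONS = ("species_month", "species_midpoint")
BOUNDARY_RULES = ("quantile", "minmax")


@dataclass(frozen=True)
class BoundaryRule:
    """Configuration of the domain boundary rule.

    q_low : lower tail fraction in (0, 0.5); the upper tail is 1 - q_low.
    record_definition : what counts as one cumulative flowering record.
    rule : "quantile" (default) or the legacy "minmax" whole-season rule.
    """

    q_low: float = 0.05
    record_definition: str = "species_month"
    rule: str = "quantile"

    def __post_init__(self) -> None:
        if self.rule not in BOUNDARY_RULES:
            raise ValueError(f"rule must be one of {BOUNDARY_RULES}, got {self.rule!r}")
        if not 0 < self.q_low < 0.5:
            raise ValueError(f"q_low must lie in (0, 0.5), got {self.q_low}")
        if self.record_definition not in RECORD_DEFINITIONS:
            raise ValueError(
                f"record_definition must be one of {RECORD_DEFINITIONS}, "
                f"got {self.record_definition!r}"
            )

    @property
    def q_high(self) -> float:
        return 1.0 - self.q_low


def _monthly_record_counts(
    records: Sequence[FloweringRecord], record_definition: str
) -> np.ndarray:
    counts = np.zeros(12)
    if record_definition == "species_month":
        for rec in records:
            for m in rec.months():
                counts[m - 1] += 1
    else:  # species_midpoint: one record per species, at its midpoint month
        for rec in records:
            mid = to_range(rec).midpoint
            # half-month midpoints round to the earlier month; midpoint 0.5
            # (the Dec/Jan seam) belongs to January
            m = int(np.ceil(mid)) if mid >= 1 else 1
            counts[m - 1] += 1
    return counts


def cumulative_distribution(
    records: Sequence[FloweringRecord], record_definition: str = "species_month"
) -> np.ndarray:
    """Cumulative fraction of flowering records by calendar month (Jan..Dec).

    Non-decreasing 12-vector ending at 1.0.
    """
    if len(records) == 0:
        raise ValueError("no records")
    counts = _monthly_record_counts(records, record_definition)
    total = counts.sum()
    return np.cumsum(counts) / total


def compute_domain(
    records: Sequence[FloweringRecord], rule: BoundaryRule | None = None
) -> TemporalDomain:
    """Set the temporal domain for one region's records.

    Quantile rule: start = earliest month with cumulative fraction > q_low;
    end = earliest month with cumulative fraction >= q_high. Boundaries
    resolve at whole months, so ties are deterministic; single-month domains
    are legal.
    """
    rule = rule or BoundaryRule()
    if len(records) == 0:
        raise ValueError("no records")
    if rule.rule == "minmax":
        first = min(r.first_month for r in records)
        last = max(r.last_month for r in records)
        if last < first:
            last += 12
        return TemporalDomain(first, last)
    cum = cumulative_distribution(records, rule.record_definition)
    # strict exceedance below, reach-or-exceed above (tolerance for float sums)
    eps = 1e-12
    start = int(np.argmax(cum > rule.q_low + eps)) + 1
    end = int(np.argmax(cum >= rule.q_high - eps)) + 1
    return TemporalDomain(start, end)
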