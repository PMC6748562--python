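"""Summary arithmetic with the one-decimal rounding convention.

All percentages reported anywhere in the package go through :func:`pct`:
one decimal place, rounding half away from zero, computed in decimal
arithmetic so printed-count pairs reproduce bit-exactly (e.g. 85/201 ->
42.3, 47/55 -> 85.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

__all__ = ["pct", "PercentSummary", "identification_timeseries"]


def pct(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded to one decimal, half away from zero."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    value = (Decimal(numerator) * 100) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PercentSummary:
    """A count pair with its one-decimal percentage, e.g. ``42.3% (85/201)``."""

    numerator: int
    denominator: int

    @property
    def pct(self) -> float:
        return pct(self.numerator, self.denominator)

    def __str__(self) -> str:
        return f"{self.pct}% ({self.numerator}/{self.denominator})"


def identification_timeseries(
    queries,
    records,
    years: Sequence[int],
    views,
    threshold_pct: Optional[float] = None,
    min_overlap_bp: Optional[int] = None,
    scores: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Identified percentage per (year, view): any category except no-match.

    One row per (year, view) with the sequenced count, identified count and
    one-decimal percentage — the growth-curve table.
    """
    from . import concordance, matcher  # local import to avoid a cycle

    table = concordance.concordance_table(
        queries,
        records,
        years,
        views,
        threshold_pct if threshold_pct is not None else matcher.DEFAULT_THRESHOLD_PCT,
        min_overlap_bp if min_overlap_bp is not None else matcher.DEFAULT_MIN_OVERLAP_BP,
        scores=scores,
    )
    return table[["year", "view", "n_sequenced", "n_identified", "pct_identified"]].copy()
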