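"""Two-period comparison of index builds on the common-measure subset.

Each period is built independently — standardized and ranked within itself
— using the identical reduced registry (the measures available in both
periods) and identical build configuration. Because ranking is
within-period, cross-period level differences reflect changes in rank
structure, not absolute change in raw measures; a pooled build is available
for users who need comparable scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BuildConfig, IndexResult, build_index
from .registry import MeasureRegistry, subset_by_period

__all__ = ["PeriodComparison", "build_reduced_pair", "compare_periods"]


@dataclass(frozen=True)
class PeriodComparison:
    """Per-tract and per-domain score changes between two periods.

    Deltas are period 2 minus period 1, in index points, computed over the
    tracts present in both periods. Tracts whose composite moved by more
    than ``gain_threshold`` points are flagged as notable gains or declines;
    domains whose mean score moved by more than ``domain_threshold`` points
    are flagged likewise.
    """

    tract_delta: pd.Series
    mean_delta: float
    domain_mean_delta: dict[str, float]
    gains: tuple[str, ...]
    declines: tuple[str, ...]
    flagged_domains: tuple[str, ...]
    gain_threshold: float
    domain_threshold: float

    def to_dict(self) -> dict:
        return {
            "mean_delta": self.mean_delta,
            "n_shared_tracts": int(len(self.tract_delta)),
            "gain_threshold": self.gain_threshold,
            "domain_threshold": self.domain_threshold,
            "gains": list(self.gains),
            "declines": list(self.declines),
            "domain_mean_delta": dict(self.domain_mean_delta),
            "flagged_domains": list(self.flagged_domains),
        }


def build_reduced_pair(
    table_1: pd.DataFrame,
    table_2: pd.DataFrame,
    registry: MeasureRegistry,
    config: BuildConfig | None = None,
) -> tuple[IndexResult, IndexResult]:
    """Build both periods with the identical common-measure registry.

    The registry is reduced to its earlier-period measures (37 under the
    packaged default); measures present only in the later period are
    ignored. Each period is preprocessed, standardized, and ranked within
    itself.
    """
    reduced = subset_by_period(registry, "period_1")
    for label, table in (("period 1", table_1), ("period 2", table_2)):
        missing = [m for m in reduced.measure_ids if m not in table.columns]
        if missing:
            raise ValueError(f"{label} table is missing common measures: {missing}")
    keep = ["fips", "population", *reduced.measure_ids]
    result_1, _, _ = build_index(table_1[keep], reduced, config)
    result_2, _, _ = build_index(table_2[keep], reduced, config)
    return result_1, result_2


def compare_periods(
    result_1: IndexResult,
    result_2: IndexResult,
    gain_threshold: float = 10.0,
    domain_threshold: float = 3.0,
) -> PeriodComparison:
    """Classify notable tract- and domain-level changes between two builds."""
    s1, s2 = result_1.scores, result_2.scores
    shared = s1.index.intersection(s2.index)
    if shared.empty:
        raise ValueError("the two periods share no fips keys")
    delta = (s2.loc[shared] - s1.loc[shared]).rename("delta")

    gains = tuple(delta.index[delta > gain_threshold])
    declines = tuple(delta.index[delta < -gain_threshold])

    d1 = result_1.domain_scores.set_axis(pd.Index(result_1.fips, name="fips"))
    d2 = result_2.domain_scores.set_axis(pd.Index(result_2.fips, name="fips"))
    common_domains = [d for d in d1.columns if d in d2.columns]
    domain_delta = {
        d: float((d2.loc[shared, d] - d1.loc[shared, d]).mean()) for d in common_domains
    }
    flagged = tuple(d for d, v in domain_delta.items() if abs(v) > domain_threshold)

    return PeriodComparison(
        tract_delta=delta,
        mean_delta=float(delta.mean()),
        domain_mean_delta=domain_delta,
        gains=gains,
        declines=declines,
        flagged_domains=flagged,
        gain_threshold=float(gain_threshold),
        domain_threshold=float(domain_threshold),
    )
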