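"""Summary statistics and TG-119-style confidence limits for QA populations.

Populations are per-plan gamma passing rates or dose differences.  The
confidence limit convention follows the TG-119 methodology: a two-sided
limit ``mean +/- 1.96 * SD`` for dose differences, and for passing rates
the one-sided form ``CL = (100 - mean) + 1.96 * SD``, equivalently the
bound "at least ``mean - 1.96 * SD`` percent of points pass".  The SD is
the sample (n-1) standard deviation, which is what reproduces published
table summaries; reported values are rounded half-away-from-zero to one
decimal while full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import load_anchor_table

__all__ = [
    "SummaryStats",
    "round1",
    "summarize",
    "cl_two_sided",
    "cl_pass_rate",
    "load_table",
    "subset_summary",
    "summary_table",
]

#: Columns of the packaged per-plan tables that hold metrics (not keys).
METRIC_COLUMNS = ("local_2_2", "global_2_2", "global_3_2", "median_dd")


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (table convention).

    A small epsilon absorbs binary float noise so values that are an
    exact decimal half (e.g. 98.45) round up as intended.
    """
    return math.floor(abs(x) * 10 + 0.5 + 1e-7) / 10 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float | None
    minimum: float
    maximum: float

    def rounded(self) -> dict[str, float | None]:
        return {
            "Average": round1(self.mean),
            "SD": None if self.sd is None else round1(self.sd),
            "Min": round1(self.minimum),
            "Max": round1(self.maximum),
        }


def summarize(values) -> SummaryStats:
    """Mean / sample SD / min / max of a population (SD needs n >= 2)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty population")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else None
    return SummaryStats(n=int(v.size), mean=float(v.mean()), sd=sd,
                        minimum=float(v.min()), maximum=float(v.max()))


def cl_two_sided(stats: SummaryStats) -> tuple[float, float]:
    """Two-sided confidence limit ``mean +/- 1.96 * SD``."""
    if stats.sd is None:
        raise ValueError("confidence limit needs a standard deviation (n >= 2)")
    return (stats.mean - 1.96 * stats.sd, stats.mean + 1.96 * stats.sd)


def cl_pass_rate(stats: SummaryStats) -> dict[str, float]:
    """One-sided confidence limit for a passing-rate population (percent).

    Returns ``cl = (100 - mean) + 1.96 * SD`` and the equivalent bound
    ``lower_bound_pass = mean - 1.96 * SD`` ("in 95% of cases at least
    this fraction of points passes").
    """
    if stats.sd is None:
        raise ValueError("confidence limit needs a standard deviation (n >= 2)")
    return {
        "cl": (100.0 - stats.mean) + 1.96 * stats.sd,
        "lower_bound_pass": stats.mean - 1.96 * stats.sd,
    }


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged per-plan fixture table (``table1``..``table3``) or its
    printed summary (``table1_summary`` ...)."""
    return load_anchor_table(name)


def subset_summary(table: pd.DataFrame, metric: str, dataset=None, energy=None,
                   technique=None) -> SummaryStats:
    """Summarize one metric over the rows matching the given keys.

    Key arguments may be a single value or a list (e.g.
    ``dataset=["Cshape-TG119", "HN-TG119"]``).  Raises if the filter
    matches nothing.
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in table columns {list(table.columns)}")
    sel = pd.Series(True, index=table.index)
    for col, want in (("dataset", dataset), ("energy", energy), ("technique", technique)):
        if want is None:
            continue
        want = [want] if isinstance(want, str) else list(want)
        sel &= table[col].isin(want)
    rows = table[sel]
    if rows.empty:
        raise ValueError("filter matches no rows")
    return summarize(rows[metric].to_numpy())


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Average/SD/Min/Max rows for every metric column, rounded to one decimal."""
    metrics = [c for c in table.columns if c in METRIC_COLUMNS]
    out = {}
    for m in metrics:
        s = summarize(table[m].to_numpy())
        out[m] = s.rounded()
    return pd.DataFrame(out, index=["Average", "SD", "Min", "Max"]).rename_axis("statistic")
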