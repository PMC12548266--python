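"""Contingent structures, frequency tables, residency summaries, sex ratios.

A *contingent* is a set of fish sharing a migratory behavior but using the
same specific habitats — e.g. two Lake St. Clair fish spawning in different
rivers belong to different contingents.  Contingents are keyed by a route
signature such as ``"LSC→DR→LE"``: the region labels of one representative
migratory cycle, in the order first used.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import UNCLASSIFIED, BehaviorAssignment
from .sequences import MISSING, VOID, DailyStateSequence


def round_half_up(x: float) -> int:
    """Round to nearest whole number, halves away from zero (as printed tables do)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _year_signature(seq: DailyStateSequence, year: int) -> tuple[str, ...]:
    start = max(seq.start_date, dt.date(year, 1, 1))
    end = min(seq.end_date, dt.date(year, 12, 31))
    order: list[str] = []
    day = start
    while day <= end:
        s = seq.state_on(day)
        if s not in (MISSING, VOID) and (not order or order[-1] != s):
            if s not in order:
                order.append(s)
        day += dt.timedelta(days=1)
    return tuple(order)


def route_signature(regional_seq: DailyStateSequence, behavior: str) -> str:
    """Region labels of a representative cycle, in order of first use.

    One candidate signature is computed per calendar year (regions
    deduplicated, first-use order); the representative cycle is the most
    frequent signature, ties resolved toward the earliest year.  Residents
    collapse to their single region.
    """
    years = range(regional_seq.start_date.year, regional_seq.end_date.year + 1)
    sigs = [(y, _year_signature(regional_seq, y)) for y in years]
    sigs = [(y, s) for y, s in sigs if s]
    if not sigs:
        raise ValueError(f"no observed regions for {regional_seq.fish_id}")
    counts: dict[tuple[str, ...], int] = {}
    first_year: dict[tuple[str, ...], int] = {}
    for y, s in sigs:
        counts[s] = counts.get(s, 0) + 1
        first_year.setdefault(s, y)
    best = max(counts.items(), key=lambda kv: (kv[1], -first_year[kv[0]]))[0]
    return "→".join(best)


def tabulate_contingents(assignments: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Count fish per (population, behavior, signature) contingent.

    ``assignments`` needs columns ``population``, ``fish_id``, ``behavior``,
    ``signature``; UNCLASSIFIED fish are excluded.  Returns the contingent
    table and the per-population count of distinct contingents.
    """
    if assignments.empty:
        return (
            pd.DataFrame(columns=["population", "behavior", "signature", "count"]),
            pd.Series(dtype=int, name="n_contingents"),
        )
    df = assignments.loc[assignments["behavior"] != UNCLASSIFIED]
    table = (
        df.groupby(["population", "behavior", "signature"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = (
        table.groupby("population")
        .size()
        .rename("n_contingents")
    )
    return table, totals


@dataclass
class FrequencyTable:
    """Behavior × population counts with whole-percent shares and totals."""

    counts: pd.DataFrame  # behaviors as index, populations as columns
    percents: pd.DataFrame  # same shape, whole percents of column totals
    row_totals: pd.Series
    row_percents: pd.Series
    column_totals: pd.Series
    grand_total: int

    def formatted(self) -> pd.DataFrame:
        """"count (pct%)" cells plus Total column, as tables are printed."""
        out = pd.DataFrame(index=self.counts.index)
        for col in self.counts.columns:
            out[col] = [
                f"{c} ({p}%)" if c else "0"
                for c, p in zip(self.counts[col], self.percents[col])
            ]
        out["Total"] = [
            f"{c} ({p}%)" for c, p in zip(self.row_totals, self.row_percents)
        ]
        return out


def frequency_table_from_counts(counts: pd.DataFrame) -> FrequencyTable:
    """Derive percent shares and totals from a behavior × population count table.

    Percentages are recomputed from the counts (half-up to whole percent)
    against each population's classified total; the Total column uses the
    grand total.
    """
    counts = counts.astype(int)
    col_totals = counts.sum(axis=0)
    row_totals = counts.sum(axis=1)
    grand = int(counts.to_numpy().sum())
    percents = counts.copy()
    for col in counts.columns:
        denom = col_totals[col]
        percents[col] = [
            round_half_up(100.0 * c / denom) if denom else 0 for c in counts[col]
        ]
    row_percents = pd.Series(
        [round_half_up(100.0 * c / grand) if grand else 0 for c in row_totals],
        index=counts.index,
    )
    return FrequencyTable(counts, percents, row_totals, row_percents, col_totals, grand)


def behavior_frequency_table(assignments: pd.DataFrame) -> FrequencyTable:
    """Frequency table from per-fish assignments (columns population, behavior)."""
    df = assignments.loc[assignments["behavior"] != UNCLASSIFIED]
    counts = (
        df.groupby(["behavior", "population"]).size().unstack(fill_value=0).sort_index()
    )
    return frequency_table_from_counts(counts)


def lake_residency_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD percent lake time per behavior × population.

    ``assignments`` needs columns ``population``, ``behavior``,
    ``lake_residency`` (fractions) and optionally ``observed_years``.
    Sample SD (ddof=1) is reported; groups of one report the mean only.
    Groups whose mean observed span is under two full migratory cycles of a
    biennial behavior are flagged as potentially truncated.
    """
    df = assignments.loc[assignments["behavior"] != UNCLASSIFIED].copy()
    rows = []
    for (pop, beh), g in df.groupby(["population", "behavior"], sort=True):
        pct = 100.0 * g["lake_residency"].astype(float)
        n = len(g)
        mean = float(pct.mean())
        sd = float(pct.std(ddof=1)) if n > 1 else None
        truncated = False
        if "observed_years" in g.columns and beh.startswith("intermittent"):
            truncated = bool(g["observed_years"].astype(float).mean() < 4.0)
        rows.append(
            {
                "population": pop,
                "behavior": beh,
                "n": n,
                "mean_pct_lake": mean,
                "sd_pct_lake": sd,
                "possibly_truncated_cycle": truncated,
            }
        )
    return pd.DataFrame(rows)


def sex_ratio_test(
    observed_m: int, observed_f: int, population_ratio_m_to_f: float
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of a behavior's sex ratio to its population.

    Expected counts are n·r/(1+r) males and n/(1+r) females for a
    population ratio of r males per female; returns (chi2, df=1, p).
    Unknown-sex fish must be excluded by the caller.
    """
    n = observed_m + observed_f
    if n < 1:
        raise ValueError("need at least one sexed fish")
    r = population_ratio_m_to_f
    if r <= 0:
        raise ValueError("population ratio must be positive")
    exp_m = n * r / (1.0 + r)
    exp_f = n / (1.0 + r)
    if min(exp_m, exp_f) < 5:
        warnings.warn(
            f"expected count below 5 (m={exp_m:.2f}, f={exp_f:.2f}); "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    chi2 = (observed_m - exp_m) ** 2 / exp_m + (observed_f - exp_f) ** 2 / exp_f
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), 1, p
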