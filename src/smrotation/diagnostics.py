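"""Slope first-difference diagnostics.

Under SM-type development the Gompertz slope alpha rises over time, so a
negative first difference alpha(t) - alpha(t-1) marks a period whose change
runs against the model — the "N" flag.  Periods flagged simultaneously in
several populations point at shared external shocks (wars, pandemics)
rather than country-specific noise.

Flags are computed on full-precision slopes; a zero difference is NONNEG
(only strictly negative changes contradict the model).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import DegenerateDataError
from .gompertz_fit import GompertzFit
from .hmd_io import PeriodInterval


class DiffFlag(enum.Enum):
    NEG = "NEG"
    NONNEG = "NONNEG"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class SlopeDiffRecord:
    """First difference of alpha into ``period`` from the preceding one."""

    period: PeriodInterval
    diff: float  # NaN when UNDEFINED
    flag: DiffFlag

    def __post_init__(self) -> None:
        if self.flag is DiffFlag.UNDEFINED:
            if not math.isnan(self.diff):
                raise ValueError("UNDEFINED record must carry NaN diff")
        elif (self.diff < 0) != (self.flag is DiffFlag.NEG):
            raise ValueError(f"flag {self.flag} inconsistent with diff {self.diff}")


def first_differences(fits: list[GompertzFit]) -> list[SlopeDiffRecord]:
    """One record per fit: the series' first record is UNDEFINED, then
    ``diff = alpha(t) - alpha(t-1)`` with flag NEG iff strictly negative.

    Input must already be period-ordered (strictly increasing start years).
    """
    if len(fits) < 2:
        raise DegenerateDataError("need >= 2 period fits for first differences")
    starts = [f.period.start_year for f in fits]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("fits must be strictly period-ordered")
    records = [SlopeDiffRecord(fits[0].period, math.nan, DiffFlag.UNDEFINED)]
    for prev, cur in zip(fits, fits[1:]):
        diff = cur.alpha - prev.alpha
        flag = DiffFlag.NEG if diff < 0 else DiffFlag.NONNEG
        records.append(SlopeDiffRecord(cur.period, diff, flag))
    return records


def concordant_negative_periods(
    series: list[list[SlopeDiffRecord]],
) -> list[str]:
    """Period labels flagged NEG in every supplied population series.

    Matching is by canonical label equality; a period absent from any
    series is excluded.  Output is in chronological order.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 population series")
    neg_sets = [
        {r.period.label: r.period for r in recs if r.flag is DiffFlag.NEG}
        for recs in series
    ]
    common = set(neg_sets[0])
    for s in neg_sets[1:]:
        common &= set(s)
    return [
        label
        for label in sorted(common, key=lambda lb: neg_sets[0][lb].start_year)
    ]


def write_diffs_csv(
    records_by_population: dict[str, list[SlopeDiffRecord]], path
) -> None:
    """CSV dump: population, period, diff (full precision), flag."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["population", "period", "diff", "flag"])
        for pop, records in records_by_population.items():
            for rec in records:
                writer.writerow(
                    [
                        pop,
                        rec.period.label,
                        "" if math.isnan(rec.diff) else repr(rec.diff),
                        rec.flag.value,
                    ]
                )
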