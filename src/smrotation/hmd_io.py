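"""HMD-style mortality file parsing and parameter-table CSV round-tripping.

The Human Mortality Database distributes period death rates as plain text:
a short preamble, then a whitespace-separated table with columns
``Year  Age  Female  Male  Total``.  In 1x5 layout the ``Year`` cell is a
calendar range such as ``1950-1954`` (single years are accepted too) and
``Age`` runs over one-year classes ``0 .. 109, 110+``.  Missing rates are
marked ``.``.

This module reads such files into a :class:`MortalitySurface` and reads /
writes the pipeline's per-period Gompertz parameter tables as CSV.  The CSV
carries both display-rounded columns (slope to 4 decimals, intercept to 2,
R^2 to 4) and full-precision companions so that write -> read is the
identity on the numbers that matter.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import HMDFormatError, MisalignedTableError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .diagnostics import SlopeDiffRecord
    from .gompertz_fit import GompertzFit

logger = logging.getLogger(__name__)

EN_DASH = "–"

_YEAR_RANGE_RE = re.compile(r"^(\d{4})\s*[-–]\s*(\d{4})$")
_SINGLE_YEAR_RE = re.compile(r"^\d{4}$")


@dataclass(frozen=True, order=True)
class PeriodInterval:
    """A calendar period [start_year, end_year], both inclusive.

    The canonical label uses an en-dash (``1751–1754``); a plain hyphen is
    accepted when parsing.  Single-year periods are allowed (start == end)
    so 1x1 files load too.
    """

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError(
                f"period end {self.end_year} precedes start {self.start_year}"
            )

    @property
    def label(self) -> str:
        if self.start_year == self.end_year:
            return str(self.start_year)
        return f"{self.start_year}{EN_DASH}{self.end_year}"

    @classmethod
    def parse(cls, token: str) -> "PeriodInterval":
        token = token.strip().rstrip("*")
        m = _YEAR_RANGE_RE.match(token)
        if m:
            return cls(int(m.group(1)), int(m.group(2)))
        if _SINGLE_YEAR_RE.match(token):
            year = int(token)
            return cls(year, year)
        raise HMDFormatError(f"unparseable Year token: {token!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass
class MortalitySurface:
    """An age x period grid of central death rates for one population.

    ``rates`` is a DataFrame indexed by integer age with one column per
    period label; missing cells are NaN.  ``open_ended_ages`` records ages
    parsed from open intervals such as ``110+``.
    """

    population_label: str
    periods: list[PeriodInterval]
    ages: np.ndarray
    rates: pd.DataFrame
    open_ended_ages: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        if len(self.ages) and np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        labels = [p.label for p in self.periods]
        if len(set(labels)) != len(labels):
            raise ValueError("period labels must be unique")
        starts = [p.start_year for p in self.periods]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("periods must be strictly increasing by start year")
        for a, b in zip(self.periods, self.periods[1:]):
            if b.start_year <= a.end_year:
                raise ValueError(f"overlapping periods {a.label} and {b.label}")
        if self.rates.shape != (len(self.ages), len(self.periods)):
            raise ValueError("rates grid does not match |ages| x |periods|")
        with np.errstate(invalid="ignore"):
            if (self.rates.to_numpy() < 0).any():
                raise ValueError("mortality rates must be nonnegative")

    @property
    def period_labels(self) -> list[str]:
        return [p.label for p in self.periods]

    def period_by_label(self, label: str) -> PeriodInterval:
        for p in self.periods:
            if p.label == label or p.label.replace(EN_DASH, "-") == label.replace(
                EN_DASH, "-"
            ):
                return p
        raise KeyError(f"no period labelled {label!r}")

    def rate(self, age: int, period: PeriodInterval) -> float:
        return float(self.rates.at[age, period.label])


def _parse_age(token: str) -> tuple[int, bool]:
    token = token.strip()
    if token.endswith("+"):
        return int(token[:-1]), True
    try:
        return int(token), False
    except ValueError as exc:
        raise HMDFormatError(f"unparseable Age token: {token!r}") from exc


def read_hmd_mx(path, column: str = "Total", population_label: str | None = None) -> MortalitySurface:
    """Read an HMD Mx period file (1x1 or 1x5 layout) into a surface.

    Parameters
    ----------
    path : str or Path
        Whitespace-delimited text file whose header row names at least
        ``Year``, ``Age`` and the requested rate column.  Preamble lines
        before the header are skipped.
    column : {"Female", "Male", "Total"}
        Which rate column to load.  The combined-sex ``Total`` column is the
        default used throughout the analysis.

    Any non-numeric rate token (the HMD marker ``.`` included) becomes a
    missing cell, with a warning logged, so minor dialect drift does not
    abort a run.  Duplicate (age, period) cells are an error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    header_idx = None
    header: list[str] = []
    for i, line in enumerate(lines):
        toks = line.split()
        if "Year" in toks and "Age" in toks:
            header_idx, header = i, toks
            break
    if header_idx is None:
        raise HMDFormatError(f"{path}: no header row naming Year and Age")
    if column not in header:
        raise HMDFormatError(
            f"{path}: unknown column {column!r}; header has {header}"
        )
    year_col, age_col, rate_col = (
        header.index("Year"),
        header.index("Age"),
        header.index(column),
    )

    cells: dict[tuple[int, str], float] = {}
    periods: dict[str, PeriodInterval] = {}
    ages_seen: set[int] = set()
    open_ages: set[int] = set()
    for lineno, line in enumerate(lines[header_idx + 1 :], header_idx + 2):
        toks = line.split()
        if not toks:
            continue
        if len(toks) <= max(year_col, age_col, rate_col):
            raise HMDFormatError(f"{path}:{lineno}: short row {line!r}")
        period = PeriodInterval.parse(toks[year_col])
        age, is_open = _parse_age(toks[age_col])
        if is_open:
            open_ages.add(age)
        token = toks[rate_col]
        try:
            rate = float(token)
        except ValueError:
            if token != ".":
                logger.warning(
                    "%s:%d: non-numeric rate %r at age %d, period %s -> missing",
                    path, lineno, token, age, period.label,
                )
            rate = math.nan
        key = (age, period.label)
        if key in cells:
            raise HMDFormatError(
                f"{path}:{lineno}: duplicate cell age {age}, period {period.label}"
            )
        cells[key] = rate
        periods.setdefault(period.label, period)
        ages_seen.add(age)

    if not cells:
        raise HMDFormatError(f"{path}: no data rows")

    ordered_periods = sorted(periods.values(), key=lambda p: p.start_year)
    ages = np.array(sorted(ages_seen))
    grid = pd.DataFrame(
        np.nan, index=ages, columns=[p.label for p in ordered_periods]
    )
    for (age, plabel), rate in cells.items():
        grid.at[age, plabel] = rate

    label = population_label or str(path)
    return MortalitySurface(
        population_label=label,
        periods=ordered_periods,
        ages=ages,
        rates=grid,
        open_ended_ages=frozenset(open_ages),
    )


def write_mx(surface: MortalitySurface, path) -> None:
    """Write a surface in the HMD Mx text dialect (so simulated surfaces can
    re-enter the pipeline through :func:`read_hmd_mx`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{surface.population_label}, Death rates (period 1x5)\n\n")
        fh.write(f"{'Year':>12} {'Age':>6} {'Total':>12}\n")
        for p in surface.periods:
            ytok = (
                str(p.start_year)
                if p.start_year == p.end_year
                else f"{p.start_year}-{p.end_year}"
            )
            for age in surface.ages:
                r = surface.rates.at[age, p.label]
                atok = f"{age}+" if age in surface.open_ended_ages else str(age)
                # scientific notation: fixed 8-decimal HMD style truncates
                # small old-age rates enough to perturb refits
                rtok = "." if (isinstance(r, float) and math.isnan(r)) else f"{r:.12e}"
                fh.write(f"{ytok:>12} {atok:>6} {rtok:>12}\n")


_TABLE_COLUMNS = [
    "period", "a", "first_diff", "sign", "ln_m0", "r2",
    "a_full", "first_diff_full", "ln_m0_full", "r2_full", "n_ages_used",
]


def _fmt(value: float | None, ndec: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{round(value, ndec):.{ndec}f}"


def write_params_table(
    fits: Sequence["GompertzFit"],
    diffs: Sequence["SlopeDiffRecord"] | None,
    path,
) -> None:
    """Write the per-period parameter table as CSV.

    Columns mirror the conventional results layout (period, slope ``a``,
    first difference, sign flag, ``ln_m0``, R^2), display-rounded to
    4/4/2/4 decimals; full-precision companion columns preserve the exact
    fitted values for round-tripping.  ``diffs``, when given, must align
    one-to-one with ``fits`` by period.
    """
    from .diagnostics import DiffFlag  # local import: avoids cycle

    if diffs is not None:
        if len(diffs) != len(fits):
            raise MisalignedTableError(
                f"{len(diffs)} diff records for {len(fits)} fits"
            )
        for fit, rec in zip(fits, diffs):
            if rec.period.label != fit.period.label:
                raise MisalignedTableError(
                    f"diff record period {rec.period.label} does not match "
                    f"fit period {fit.period.label}"
                )

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TABLE_COLUMNS)
        for i, fit in enumerate(fits):
            rec = diffs[i] if diffs is not None else None
            if rec is None or rec.flag is DiffFlag.UNDEFINED:
                diff_disp, diff_full, sign = "", "", "x"
            else:
                diff_disp = _fmt(rec.diff, 4)
                diff_full = repr(rec.diff)
                sign = "N" if rec.flag is DiffFlag.NEG else ""
            writer.writerow(
                [
                    fit.period.label,
                    _fmt(fit.alpha, 4),
                    diff_disp,
                    sign,
                    _fmt(fit.ln_m0, 2),
                    _fmt(fit.r2, 4),
                    repr(fit.alpha),
                    diff_full,
                    repr(fit.ln_m0),
                    "" if math.isnan(fit.r2) else repr(fit.r2),
                    fit.n_ages_used if fit.n_ages_used else "",
                ]
            )


def read_params_table(path, population_label: str | None = None) -> list["GompertzFit"]:
    """Read a parameter-table CSV back into period-ordered Gompertz fits.

    Requires columns ``period``, ``a`` and ``ln_m0`` (an ``R^2``-style
    column is used when present, tolerated when absent).  Full-precision
    companion columns, when present, take precedence over the rounded
    display columns.  Rows are returned ordered by period start year
    regardless of file order.
    """
    from .gompertz_fit import GompertzFit  # local import: avoids cycle

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    for mandatory in ("period", "a", "ln_m0"):
        if mandatory not in df.columns:
            raise HMDFormatError(
                f"{path}: parameter table is missing mandatory column {mandatory!r}"
            )

    def pick(row, full_col, disp_col):
        if full_col in df.columns and row[full_col] != "":
            return float(row[full_col])
        if row[disp_col] == "":
            return math.nan
        return float(row[disp_col].replace("−", "-"))

    fits = []
    label = population_label or str(path)
    for _, row in df.iterrows():
        period = PeriodInterval.parse(row["period"])
        alpha = pick(row, "a_full", "a")
        ln_m0 = pick(row, "ln_m0_full", "ln_m0")
        r2 = pick(row, "r2_full", "r2") if ("r2" in df.columns or "r2_full" in df.columns) else math.nan
        n_used = 0
        if "n_ages_used" in df.columns and row["n_ages_used"] != "":
            n_used = int(row["n_ages_used"])
        fits.append(
            GompertzFit(
                population_label=label,
                period=period,
                alpha=alpha,
                ln_m0=ln_m0,
                r2=r2,
                n_ages_used=n_used,
                age_window=None,
            )
        )
    fits.sort(key=lambda f: f.period.start_year)
    return fits
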