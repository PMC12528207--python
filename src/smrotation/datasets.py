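"""Bundled long-run Gompertz parameter series.

The package ships published per-period Gompertz parameters (slope ``a`` and
intercept ``ln m0``, HMD-derived, combined sexes, ages 40-95) for Sweden
(1751-2023, 55 five-year periods) and France (42 periods; the table's
shared period labels are kept, although the French series actually starts
1816-1819 and ends 2020-2021).  Values are printed-precision: ``a`` to 4
decimals, ``ln m0`` to 2 — second-level statistics refit from them match
full-precision results only within the corresponding rounding tolerance.

A Netherlands series (1850-2021) exists in the same literature but is not
bundled here; :func:`load_netherlands_params` says so explicitly rather
than silently returning nothing.
"""

from __future__ import annotations

from importlib import resources

from .gompertz_fit import GompertzFit
from .hmd_io import read_params_table


def _load(name: str, label: str) -> list[GompertzFit]:
    ref = resources.files("smrotation") / "data" / name
    with resources.as_file(ref) as path:
        return read_params_table(path, population_label=label)


def load_sweden_params() -> list[GompertzFit]:
    """Sweden, 55 periods 1751–1754 … 2020–2023."""
    return _load("sweden_gompertz_params.csv", "Sweden")


def load_france_params() -> list[GompertzFit]:
    """France, 42 periods (first table row 1815–1819, last 2020–2023)."""
    return _load("france_gompertz_params.csv", "France")


def load_netherlands_params() -> list[GompertzFit]:
    """Netherlands series — not bundled.

    The published per-period parameter block for the Netherlands was not
    available to this package at build time, so there is nothing to load;
    raising keeps downstream checks honest instead of silently passing.
    """
    raise FileNotFoundError(
        "the Netherlands per-period Gompertz parameter series is not bundled "
        "with this package; supply your own CSV via read_params_table()"
    )
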