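"""Per-period Gompertz fitting.

Above roughly age 40 the log of the force of mortality rises linearly with
age::

    ln mu(x) = ln m0 + alpha * x

``alpha`` (per year of age) is the population aging rate; ``ln m0`` is the
extrapolated log intensity at age 0.  Both are estimated per calendar
period by unweighted ordinary least squares on (age, ln rate) points inside
an inclusive age window, 40-95 by default.  Point estimation only: mortality
residuals are U-shaped rather than Gaussian, so no inference is attached.

The estimator is scikit-learn compatible (:class:`GompertzRegression`);
:func:`fit_gompertz` and :func:`fit_all_periods` are thin functional
wrappers producing :class:`GompertzFit` records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import DegenerateDataError
from .hmd_io import MortalitySurface, PeriodInterval

logger = logging.getLogger(__name__)

DEFAULT_AGE_WINDOW = (40, 95)


@dataclass(frozen=True)
class GompertzFit:
    """Fitted Gompertz line for one population-period.

    ``n_ages_used`` may be 0 when the fit was read back from a parameter
    table that did not record it; ``age_window`` may likewise be None.
    """

    population_label: str
    period: PeriodInterval
    alpha: float
    ln_m0: float
    r2: float
    n_ages_used: int = 0
    age_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_ages_used and self.n_ages_used < 3:
            raise ValueError("a Gompertz fit needs at least 3 age points")
        if not math.isnan(self.r2) and not (-1e-12 <= self.r2 <= 1 + 1e-12):
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")
        if self.age_window is not None and self.age_window[0] >= self.age_window[1]:
            raise ValueError("age window min must be below max")


class GompertzRegression(RegressorMixin, BaseEstimator):
    """OLS fit of log mortality intensity on age.

    scikit-learn interface: ``X`` is the (n, 1) age column, ``y`` the log
    rates.  Fitted attributes: ``alpha_`` (slope per year of age),
    ``ln_m0_`` (intercept at age 0), ``r2_`` (in-sample coefficient of
    determination), ``n_points_``.

    Degenerate inputs: fewer than 3 points or a single distinct age raise
    :class:`DegenerateDataError`.  If all responses are equal (zero total
    sum of squares) the fitted line is flat and ``r2_`` is defined as 1.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=1, ensure_2d=True)
        if X.shape[1] != 1:
            raise ValueError("GompertzRegression expects a single age feature")
        x = X[:, 0].astype(float)
        if x.size < 3:
            raise DegenerateDataError(
                f"need >= 3 (age, ln rate) points, got {x.size}"
            )
        if np.unique(x).size < 2:
            raise DegenerateDataError("all ages identical: slope undefined")
        coef, intercept, r2 = _ols_line(x, y)
        self.alpha_ = coef
        self.ln_m0_ = intercept
        self.r2_ = r2
        self.n_points_ = int(x.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        X = check_array(X, ensure_2d=True)
        return self.ln_m0_ + self.alpha_ * X[:, 0]


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression OLS via lstsq; returns (slope, intercept, r2)."""
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (intercept + slope * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - float(np.sum(resid**2)) / sst
    return float(slope), float(intercept), r2


def extract_log_rate_points(
    surface: MortalitySurface,
    period: PeriodInterval,
    age_window: tuple[int, int] = DEFAULT_AGE_WINDOW,
    midpoint_ages: bool = False,
) -> list[tuple[float, float]]:
    """Collect (age, ln rate) pairs for one period inside an age window.

    Only present, strictly positive rates contribute; zero and missing
    cells are excluded (ln of 0 is undefined) and logged.  The age
    coordinate is the integer age-class label, or the class midpoint
    ``x + 0.5`` when ``midpoint_ages`` is set (sensitivity switch).
    """
    lo, hi = age_window
    label = period.label
    if label not in surface.rates.columns:
        raise KeyError(f"period {label} not in surface {surface.population_label}")
    points: list[tuple[float, float]] = []
    for age in surface.ages:
        if not (lo <= age <= hi):
            continue
        rate = surface.rates.at[age, label]
        if isinstance(rate, float) and math.isnan(rate):
            logger.info("excluded missing cell age %d, period %s", age, label)
            continue
        if rate <= 0:
            logger.info(
                "excluded nonpositive rate %g at age %d, period %s", rate, age, label
            )
            continue
        coord = age + 0.5 if midpoint_ages else float(age)
        points.append((coord, math.log(rate)))
    if len(points) < 3:
        raise DegenerateDataError(
            f"period {label}: only {len(points)} usable points in "
            f"ages [{lo}, {hi}] (need >= 3)"
        )
    return points


def fit_gompertz(
    points: list[tuple[float, float]],
    population_label: str = "",
    period: PeriodInterval | None = None,
    age_window: tuple[int, int] | None = None,
) -> GompertzFit:
    """Fit one Gompertz line by OLS on (age, ln rate) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (age, ln rate) pairs")
    model = GompertzRegression().fit(pts[:, :1], pts[:, 1])
    return GompertzFit(
        population_label=population_label,
        period=period if period is not None else PeriodInterval(0, 0),
        alpha=model.alpha_,
        ln_m0=model.ln_m0_,
        r2=model.r2_,
        n_ages_used=model.n_points_,
        age_window=age_window,
    )


def fit_all_periods(
    surface: MortalitySurface,
    age_window: tuple[int, int] = DEFAULT_AGE_WINDOW,
    midpoint_ages: bool = False,
) -> list[GompertzFit]:
    """Fit every period of a surface, in period order.

    Periods that fail the >= 3 usable points precondition are skipped with
    a warning; an empty result is an error.
    """
    fits: list[GompertzFit] = []
    for period in surface.periods:
        try:
            points = extract_log_rate_points(
                surface, period, age_window, midpoint_ages=midpoint_ages
            )
        except DegenerateDataError as exc:
            logger.warning(
                "skipping period %s of %s: %s",
                period.label, surface.population_label, exc,
            )
            continue
        fits.append(
            fit_gompertz(
                points,
                population_label=surface.population_label,
                period=period,
                age_window=age_window,
            )
        )
    if not fits:
        raise DegenerateDataError(
            f"no period of {surface.population_label} yielded a Gompertz fit"
        )
    return fits


def predict_ln_mu(fit: GompertzFit, age: float) -> float:
    """Log mortality intensity of a fitted line at a given age."""
    return fit.ln_m0 + fit.alpha * age
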