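"""The Strehler-Mildvan (SM) correlation and rotation-point geometry.

Across calendar periods the two Gompertz parameters trade off linearly::

    ln m0(alpha) = YA - A * alpha

so successive Gompertz lines approximately rotate about a fixed point
(A, YA): at age A the log mortality intensity stays near YA while younger
ages improve and the slope steepens.  The regression of ``ln m0`` (response)
on ``alpha`` (predictor) is fitted by unweighted OLS; the rotation age is
minus the slope.

The residual band is the pair of lines parallel to the SM fit shifted by
the extreme residuals r_max and r_min on the log scale.  Its width is
reported as the ratio L2/L1 = exp(r_max - r_min) between the upper and
lower band lines, which is independent of where on the axis it is read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import DegenerateDataError, ParallelLinesError
from .gompertz_fit import GompertzFit, _ols_line


class StrehlerMildvanRegression(RegressorMixin, BaseEstimator):
    """OLS fit of the SM correlation, ln m0 on alpha.

    scikit-learn interface: ``X`` is the (n, 1) column of Gompertz slopes,
    ``y`` the intercepts ``ln m0``.  Fitted attributes:

    rotation_age_
        A in years (minus the regression slope).
    rotation_level_
        YA, the log intensity at the rotation point (regression intercept).
    r2_, residuals_, r_max_, r_min_, band_ratio_
        Goodness of fit, per-input residuals, their extremes, and
        exp(r_max - r_min).
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=1, ensure_2d=True)
        if X.shape[1] != 1:
            raise ValueError("StrehlerMildvanRegression expects a single feature")
        a = X[:, 0].astype(float)
        if a.size < 3:
            raise DegenerateDataError(f"need >= 3 period fits, got {a.size}")
        if np.unique(a).size < 2:
            raise DegenerateDataError(
                "all Gompertz slopes equal: SM line is vertical, rotation age undefined"
            )
        slope, intercept, r2 = _ols_line(a, y)
        self.slope_ = slope
        self.rotation_age_ = -slope
        self.rotation_level_ = intercept
        self.r2_ = r2
        self.residuals_ = y - (intercept + slope * a)
        self.r_max_ = float(self.residuals_.max())
        self.r_min_ = float(self.residuals_.min())
        self.band_ratio_ = float(math.exp(self.r_max_ - self.r_min_))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "rotation_age_")
        X = check_array(X, ensure_2d=True)
        return self.rotation_level_ - self.rotation_age_ * X[:, 0]


@dataclass
class SMFit:
    """Second-level SM regression result across the periods of one population."""

    population_label: str
    A_years: float
    YA: float
    r2: float
    residuals: dict[str, float] = field(default_factory=dict)
    r_max: float = 0.0
    r_min: float = 0.0
    band_ratio: float = 1.0

    @property
    def slope(self) -> float:
        return -self.A_years

    def to_dict(self) -> dict:
        return {
            "population": self.population_label,
            "A_years": self.A_years,
            "YA": self.YA,
            "r2": self.r2,
            "band_ratio": self.band_ratio,
            "residuals": dict(self.residuals),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def fit_sm(fits: list[GompertzFit], population_label: str | None = None) -> SMFit:
    """Fit the SM correlation across per-period Gompertz fits.

    Residuals are keyed by period label in input order.  Requires at least
    3 fits with at least 2 distinct slopes.
    """
    if len(fits) < 3:
        raise DegenerateDataError(f"need >= 3 period fits, got {len(fits)}")
    alphas = np.array([f.alpha for f in fits], dtype=float)
    ln_m0s = np.array([f.ln_m0 for f in fits], dtype=float)
    model = StrehlerMildvanRegression().fit(alphas[:, None], ln_m0s)
    label = population_label or (fits[0].population_label if fits else "")
    return SMFit(
        population_label=label,
        A_years=model.rotation_age_,
        YA=model.rotation_level_,
        r2=model.r2_,
        residuals={f.period.label: float(r) for f, r in zip(fits, model.residuals_)},
        r_max=model.r_max_,
        r_min=model.r_min_,
        band_ratio=model.band_ratio_,
    )


def band_ratio(smfit: SMFit) -> float:
    """Width of the residual band, exp(r_max - r_min); 1 iff all residuals equal."""
    if not smfit.residuals:
        raise DegenerateDataError("SM fit has no residuals")
    return float(math.exp(smfit.r_max - smfit.r_min))


def rotation_point_intensity(fit: GompertzFit, smfit: SMFit) -> float:
    """Log intensity of one period's Gompertz line evaluated at the rotation age.

    Algebraically equals ``YA`` plus that period's SM residual, so under a
    perfect rotation every period returns exactly ``YA``.
    """
    return fit.ln_m0 + fit.alpha * smfit.A_years


def intersection_age(fit1: GompertzFit, fit2: GompertzFit) -> float:
    """Age at which two Gompertz lines cross: (ln_m0_1 - ln_m0_2)/(a2 - a1)."""
    if fit1.alpha == fit2.alpha:
        raise ParallelLinesError(
            f"equal slopes ({fit1.alpha}): lines are parallel, no intersection age"
        )
    return (fit1.ln_m0 - fit2.ln_m0) / (fit2.alpha - fit1.alpha)


def plot_sm(fits: list[GompertzFit], smfit: SMFit, path) -> None:
    """Scatter of (alpha, m0) with log vertical axis, SM line and residual band.

    Each period is one point at (alpha, exp(ln m0)); the regression line and
    the two parallel band lines through the extreme residuals are drawn on
    the same log scale, and points carry their period labels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    alphas = np.array([f.alpha for f in fits], dtype=float)
    m0s = np.exp([f.ln_m0 for f in fits])
    grid = np.linspace(alphas.min(), alphas.max(), 100)
    line = smfit.YA - smfit.A_years * grid

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(alphas, m0s, s=18, color="black", zorder=3)
    ax.plot(grid, np.exp(line), color="purple", label="SM regression")
    ax.plot(grid, np.exp(line + smfit.r_max), color="gray", ls="--", label="band L2")
    ax.plot(grid, np.exp(line + smfit.r_min), color="gray", ls="--", label="band L1")
    for f in fits:
        if f.period.label:
            ax.annotate(
                f.period.label, (f.alpha, math.exp(f.ln_m0)),
                fontsize=6, xytext=(2, 2), textcoords="offset points",
            )
    ax.set_yscale("log")
    ax.set_xlabel(r"Gompertz slope $\alpha$ (per year of age)")
    ax.set_ylabel(r"$m_0$ (per person-year, log scale)")
    ax.set_title(
        f"{smfit.population_label}: A = {smfit.A_years:.1f} y, "
        f"$R^2$ = {smfit.r2:.3f}, L2/L1 = {smfit.band_ratio:.2f}"
    )
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
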