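"""Non-Bayesian estimators of the Lomax shape parameter.

Five estimators, all taking the scale as known:

* maximum likelihood        n / T
* minimum-variance unbiased (n - 1) / T
* ordinary least squares    minus the slope of ln(1 - F_hat_i) on ln(scale + x_(i))
* ridge regression          the same slope with a penalty lam added to n
* median method             -ln(0.5) / ln(1 + median(x)/scale)

The two regression estimators exploit the linearisation
ln(1 - F(x)) = -theta * ln(scale + x) + theta * ln(scale): on a probability
plot with rank-based CDF estimates F_hat_i the slope is -theta.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import Sample, SufficientStat

__all__ = [
    "PlottingPosition",
    "RidgeOptions",
    "RegressionFit",
    "mle",
    "umvue",
    "ols_fit",
    "ols_estimate",
    "ridge_fit",
    "ridge_estimate",
    "median_estimate",
]


class PlottingPosition(str, enum.Enum):
    """Rank-based CDF estimate F_hat_i at the i-th order statistic."""

    MEDIAN_RANK = "median_rank"  # (i - 0.3) / (n + 0.4)
    MEAN_RANK = "mean_rank"      # i / (n + 1)
    BLOM = "blom"                # (i - 3/8) / (n + 0.25)

    def positions(self, n: int) -> np.ndarray:
        i = np.arange(1, n + 1, dtype=float)
        if self is PlottingPosition.MEDIAN_RANK:
            return (i - 0.3) / (n + 0.4)
        if self is PlottingPosition.MEAN_RANK:
            return i / (n + 1.0)
        return (i - 0.375) / (n + 0.25)


@dataclass(frozen=True)
class RidgeOptions:
    """Ridge penalty configuration.

    ``lam_mode="fixed"`` uses ``lam`` as given.  ``lam_mode="data_driven"``
    sets lam = rho * sigma2 / (b'b) from the OLS fit, where rho = 2 (the
    number of distribution parameters), sigma2 is the OLS residual mean
    square and b'b the squared norm of the OLS coefficient vector; the
    result is clamped to (0, 1).
    """

    lam: float = 0.75
    lam_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.lam_mode not in ("fixed", "data_driven"):
            raise ValueError(f"unknown lam_mode {self.lam_mode!r}")
        if self.lam_mode == "fixed" and self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass(frozen=True)
class RegressionFit:
    """Slope/intercept of the probability-plot regression plus design sums."""

    slope: float
    intercept: float
    sum_x: float
    sum_y: float
    sum_xy: float
    sum_xx: float
    n: int


def mle(stat: SufficientStat) -> float:
    """Maximum-likelihood estimate n / T."""
    if stat.T <= 0:
        raise ValueError("degenerate sample: T = 0 (all observations zero)")
    return stat.n / stat.T


def umvue(stat: SufficientStat) -> float:
    """Minimum-variance unbiased estimate (n - 1) / T; requires n >= 2."""
    if stat.n < 2:
        raise ValueError("unbiased estimator requires n >= 2")
    if stat.T <= 0:
        raise ValueError("degenerate sample: T = 0 (all observations zero)")
    return (stat.n - 1) / stat.T


def _design(sample: Sample, scale: float, pp: PlottingPosition):
    if not (scale > 0):
        raise ValueError("scale must be > 0")
    if sample.n < 2:
        raise ValueError("regression estimators require n >= 2")
    xs = np.sort(sample.values)
    x_star = np.log(scale + xs)
    y = np.log(1.0 - pp.positions(sample.n))
    return x_star, y


def _penalised_fit(x_star: np.ndarray, y: np.ndarray, lam: float) -> RegressionFit:
    n = x_star.size
    sum_x = float(x_star.sum())
    sum_y = float(y.sum())
    sum_xy = float((x_star * y).sum())
    sum_xx = float((x_star * x_star).sum())
    denom = (n + lam) * sum_xx - sum_x * sum_x
    if denom == 0.0:
        raise ValueError("singular design: all ln(scale + x) values coincide")
    slope = ((n + lam) * sum_xy - sum_x * sum_y) / denom
    intercept = (sum_y - slope * sum_x) / (n + lam)
    return RegressionFit(slope, intercept, sum_x, sum_y, sum_xy, sum_xx, n)


def ols_fit(
    sample: Sample,
    scale: float,
    pp: PlottingPosition = PlottingPosition.MEDIAN_RANK,
) -> RegressionFit:
    """Least-squares fit of ln(1 - F_hat_i) against ln(scale + x_(i)).

    Order statistics are taken internally; the sample need not be sorted.
    """
    x_star, y = _design(sample, scale, pp)
    return _penalised_fit(x_star, y, 0.0)


def ols_estimate(
    sample: Sample,
    scale: float,
    pp: PlottingPosition = PlottingPosition.MEDIAN_RANK,
) -> float:
    """Shape estimate: minus the OLS slope."""
    return -ols_fit(sample, scale, pp).slope


def data_driven_lambda(fit: RegressionFit, x_star: np.ndarray, y: np.ndarray) -> float:
    """lam = 2 * sigma2 / (slope^2 + intercept^2) from an OLS fit, clamped to (0, 1)."""
    resid = y - fit.intercept - fit.slope * x_star
    dof = max(fit.n - 2, 1)
    sigma2 = float((resid * resid).sum()) / dof
    bb = fit.slope**2 + fit.intercept**2
    lam = 2.0 * sigma2 / bb if bb > 0 else 1.0
    return float(min(max(lam, np.finfo(float).tiny), 1.0))


def ridge_fit(
    sample: Sample,
    scale: float,
    pp: PlottingPosition = PlottingPosition.MEDIAN_RANK,
    opts: Optional[RidgeOptions] = None,
) -> RegressionFit:
    """Ridge-penalised probability-plot fit.

    The penalty enters by replacing n with (n + lam) in the normal-equation
    sums, so lam = 0 reproduces :func:`ols_fit` exactly.
    """
    opts = opts or RidgeOptions()
    x_star, y = _design(sample, scale, pp)
    lam = opts.lam
    if opts.lam_mode == "data_driven":
        lam = data_driven_lambda(_penalised_fit(x_star, y, 0.0), x_star, y)
    return _penalised_fit(x_star, y, lam)


def ridge_estimate(
    sample: Sample,
    scale: float,
    pp: PlottingPosition = PlottingPosition.MEDIAN_RANK,
    opts: Optional[RidgeOptions] = None,
) -> float:
    """Shape estimate: minus the ridge slope."""
    return -ridge_fit(sample, scale, pp, opts).slope


def median_estimate(sample: Sample, scale: float) -> float:
    """Shape estimate from the sample median.

    Solves F(x_med) = 0.5 for the shape: -ln(0.5) / ln(1 + x_med/scale).
    Even n uses the mean of the two central order statistics.
    """
    if not (scale > 0):
        raise ValueError("scale must be > 0")
    x_med = float(np.median(sample.values))
    if x_med <= 0:
        raise ValueError("degenerate sample: median is zero")
    return -math.log(0.5) / math.log1p(x_med / scale)
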