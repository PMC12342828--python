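"""First-order rate estimation from population-mean time courses.

Decay rates (mRNA degradation after rifampicin, protein removal in a
pulse-chase) are obtained by normalizing mean counts to t = 0, taking the
natural log and fitting ordinary least squares; the rate is minus the slope,
with a t-distribution 95% CI from the slope standard error. Growth rate is
the OLS slope of ln(OD600) restricted to the exponential window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .synthetic import TimeCourse

__all__ = [
    "DecayFit",
    "PooledRate",
    "ExponentialDecayEstimator",
    "GrowthRateEstimator",
    "fit_decay_rate",
    "average_replicate_rates",
    "fit_growth_rate",
]


@dataclass(frozen=True)
class DecayFit:
    """A fitted first-order removal rate (min^-1) with its 95% CI."""

    gamma: float
    ci95: tuple[float, float]
    window: tuple[float, float]
    r_squared: float
    stderr: float
    n_points: int


@dataclass(frozen=True)
class PooledRate:
    gamma: float
    ci95: tuple[float, float]
    n_replicates: int


def _ols_slope_ci(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of y on t; returns (slope, stderr, r_squared, ci_halfwidth)."""
    res = stats.linregress(t, y)
    df = len(t) - 2
    if df > 0 and np.isfinite(res.stderr) and res.stderr > 0:
        half = stats.t.ppf(0.975, df) * res.stderr
    else:
        half = 0.0
    return res.slope, res.stderr if np.isfinite(res.stderr) else 0.0, res.rvalue**2, half


class ExponentialDecayEstimator(BaseEstimator):
    """Log-linear OLS estimator of a first-order decay rate.

    Parameters
    ----------
    window : (t_start, t_end) or None. With None, a documented heuristic is
        used: fit all timepoints, then refit keeping points whose ln-mean
        residual is within 2 SD of the preliminary fit.

    Attributes (after fit)
    ----------------------
    gamma_ : decay rate, minus the fitted slope.
    ci95_ : 95% confidence interval on gamma_ (t-distribution on the slope SE).
    r_squared_, stderr_, window_, n_points_ : fit diagnostics.
    """

    def __init__(self, window: tuple[float, float] | None = None):
        self.window = window

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        order = np.argsort(t)
        t, y = t[order], y[order]
        i0 = int(np.argmin(np.abs(t)))
        if y[i0] <= 0:
            raise ValueError("mean count at t = 0 must be positive")
        y = y / y[i0]  # normalization to t = 0: slope is scale invariant

        if self.window is not None:
            lo, hi = self.window
            keep = (t >= lo) & (t <= hi)
        else:
            keep = np.ones(len(t), dtype=bool)
        if keep.sum() < 3:
            raise ValueError("need at least 3 timepoints inside the window")
        if np.any(y[keep] <= 0):
            raise ValueError("non-positive mean count inside the fitting window")
        logy = np.log(y[keep])
        tw = t[keep]

        if self.window is None and len(tw) > 3:
            slope, *_ = _ols_slope_ci(tw, logy)
            intercept = logy.mean() - slope * tw.mean()
            resid = logy - (intercept + slope * tw)
            sd = resid.std(ddof=2) if len(tw) > 2 else 0.0
            inlier = np.abs(resid) < 2.0 * sd if sd > 0 else np.ones_like(resid, bool)
            if inlier.sum() >= 3:
                tw, logy = tw[inlier], logy[inlier]

        slope, stderr, r2, half = _ols_slope_ci(tw, logy)
        self.gamma_ = -slope
        self.ci95_ = (self.gamma_ - half, self.gamma_ + half)
        self.r_squared_ = r2
        self.stderr_ = stderr
        self.window_ = (float(tw.min()), float(tw.max()))
        self.n_points_ = int(len(tw))
        return self

    def to_result(self) -> DecayFit:
        return DecayFit(
            gamma=self.gamma_,
            ci95=self.ci95_,
            window=self.window_,
            r_squared=self.r_squared_,
            stderr=self.stderr_,
            n_points=self.n_points_,
        )


def fit_decay_rate(tc: TimeCourse, window: tuple[float, float] | None = None) -> DecayFit:
    """Fit the removal rate of a :class:`TimeCourse` (see module docstring)."""
    est = ExponentialDecayEstimator(window=window).fit(tc.times, tc.mean_counts)
    return est.to_result()


def average_replicate_rates(fits: list[DecayFit]) -> PooledRate:
    """Pool replicate decay fits: arithmetic mean of the rates.

    The pooled CI half-width is the wider of (a) the mean of the replicate CI
    half-widths and (b) the t-based half-width from the spread of replicate
    rates; both notions are reported through one conservative interval.
    """
    if not fits:
        raise ValueError("need at least one fit")
    gammas = np.array([f.gamma for f in fits])
    mean = float(gammas.mean())
    half_ci = float(np.mean([(f.ci95[1] - f.ci95[0]) / 2.0 for f in fits]))
    k = len(fits)
    if k > 1:
        half_spread = float(
            stats.t.ppf(0.975, k - 1) * gammas.std(ddof=1) / np.sqrt(k)
        )
    else:
        half_spread = 0.0
    half = max(half_ci, half_spread)
    return PooledRate(gamma=mean, ci95=(mean - half, mean + half), n_replicates=k)


class GrowthRateEstimator(BaseEstimator):
    """OLS slope of ln(OD600) vs time, restricted to the exponential window.

    The default window OD600 in [0.08, 0.4] brackets balanced exponential
    growth; points outside it are dropped before fitting.
    """

    def __init__(self, od_window: tuple[float, float] = (0.08, 0.4)):
        self.od_window = od_window

    def fit(self, t, od):
        t = np.asarray(t, dtype=float)
        od = np.asarray(od, dtype=float)
        lo, hi = self.od_window
        keep = (od >= lo) & (od <= hi)
        if keep.sum() < 3:
            raise ValueError("need at least 3 OD points inside the window")
        slope, stderr, r2, half = _ols_slope_ci(t[keep], np.log(od[keep]))
        self.rate_ = slope
        self.ci95_ = (slope - half, slope + half)
        self.r_squared_ = r2
        self.n_points_ = int(keep.sum())
        return self


def fit_growth_rate(
    times, od_series, od_window: tuple[float, float] = (0.08, 0.4)
) -> float:
    """Exponential growth rate (min^-1) from an optical-density series."""
    return GrowthRateEstimator(od_window=od_window).fit(times, od_series).rate_
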