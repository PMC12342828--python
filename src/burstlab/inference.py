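"""Inference of two-stage model parameters from snapshot count distributions.

The stationary mRNA distribution of the bursty model is negative binomial;
fitting NB(r, p) to newborn-conditioned counts by maximum likelihood gives
the burst statistics directly:

    b   = (1 - p)/p          mean burst size
    k_m = gamma_m * r        burst arrival (transcription) rate

The translation rate follows from moment matching of the protein stage,
k_p = gamma_p <p>/<m>. Throughout, NB(r, p) uses the convention
mean = r(1-p)/p (the scipy.stats.nbinom convention), under which the
stationary law of the bursty model has r = k_m/gamma_m and p = 1/(1+b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .model import (  # noqa: F401  (re-exported analysis surface)
    ModelParams,
    MomentSummary,
    cv2_poisson_bound,
    cv2_theory,
    relaxation_check,
)

__all__ = [
    "NBFit",
    "NegativeBinomialEstimator",
    "filter_newborns",
    "nb_mle",
    "burst_size",
    "transcription_rate",
    "translation_rate",
    "moment_summary",
    "cv2_theory",
    "cv2_poisson_bound",
    "relaxation_check",
]

NEWBORN_AREA_MAX = 3.0  # um^2; strict upper bound of the newborn class


@dataclass(frozen=True)
class NBFit:
    """Maximum-likelihood negative binomial fit, mean = r(1-p)/p."""

    r: float
    p: float
    loglik: float
    n: int


def filter_newborns(
    snapshot: pd.DataFrame, area_max: float = NEWBORN_AREA_MAX
) -> pd.DataFrame:
    """Cells with area strictly below `area_max` (um^2).

    Newborns are the smallest-area class, for which the non-growing
    steady-state model assumptions apply.
    """
    if "area_um2" not in snapshot.columns:
        raise ValueError("snapshot must have an 'area_um2' column")
    return snapshot.loc[snapshot["area_um2"] < area_max]


def _nb_negloglik(theta: np.ndarray, counts: np.ndarray) -> float:
    log_r, logit_p = theta
    r = np.exp(log_r)
    p = special.expit(logit_p)
    ll = stats.nbinom.logpmf(counts, r, p).sum()
    return -ll if np.isfinite(ll) else 1e300


class NegativeBinomialEstimator(BaseEstimator):
    """Maximum-likelihood NB(r, p) fit to integer count data.

    Optimizes the raw-count log-likelihood over (log r, logit p) with a
    bounded quasi-Newton method from a moment-based start. Requires
    over-dispersed data (sample variance > mean); at or below the Poisson
    boundary the NB shape diverges and the fit is refused.

    Attributes (after fit): ``r_``, ``p_``, ``loglik_``, ``n_``.
    """

    def __init__(self, tol: float = 1e-10):
        self.tol = tol

    def fit(self, counts):
        counts = np.asarray(counts)
        if counts.ndim != 1 or len(counts) < 2:
            raise ValueError("counts must be a 1-D array with >= 2 values")
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(np.int64)
        if len(np.unique(counts)) < 2:
            if counts.max() == 0:
                raise ValueError("all-zero sample: NB parameters are undefined")
            raise ValueError("need at least 2 distinct count values")
        mean = counts.mean()
        var = counts.var(ddof=1)
        if var <= mean:
            raise ValueError(
                "sample variance <= mean: data are at or below the Poisson "
                "boundary, where the NB shape parameter diverges"
            )
        # moment start: mean = r(1-p)/p, var = r(1-p)/p^2
        p0 = mean / var
        r0 = mean * p0 / (1.0 - p0)
        theta0 = np.array([np.log(r0), special.logit(p0)])
        res = optimize.minimize(
            _nb_negloglik,
            theta0,
            args=(counts,),
            method="L-BFGS-B",
            options={"ftol": self.tol, "gtol": 1e-9},
        )
        self.r_ = float(np.exp(res.x[0]))
        self.p_ = float(special.expit(res.x[1]))
        self.loglik_ = float(-res.fun)
        self.n_ = int(len(counts))
        return self

    def to_result(self) -> NBFit:
        return NBFit(r=self.r_, p=self.p_, loglik=self.loglik_, n=self.n_)


def nb_mle(counts) -> NBFit:
    """MLE of NB(r, p) on raw counts (see :class:`NegativeBinomialEstimator`)."""
    return NegativeBinomialEstimator().fit(counts).to_result()


def burst_size(fit: NBFit | float) -> float:
    """Mean transcriptional burst size b = (1-p)/p from an NB fit (or p)."""
    p = fit.p if isinstance(fit, NBFit) else float(fit)
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    return (1.0 - p) / p


def p_from_burst_size(b: float) -> float:
    """Inverse of :func:`burst_size`: p = 1/(1+b)."""
    if b < 0:
        raise ValueError("burst size must be >= 0")
    return 1.0 / (1.0 + b)


def transcription_rate(fit: NBFit | float, gamma_m: float) -> float:
    """Burst arrival rate k_m = gamma_m * r."""
    if gamma_m <= 0:
        raise ValueError("gamma_m must be positive")
    r = fit.r if isinstance(fit, NBFit) else float(fit)
    return gamma_m * r


def translation_rate(gamma_p: float, mean_p: float, mean_m: float) -> float:
    """Translation rate by moment matching, k_p = gamma_p <p>/<m>."""
    if mean_m <= 0:
        raise ValueError("mean mRNA count must be positive")
    return gamma_p * mean_p / mean_m


def moment_summary(snapshot: pd.DataFrame) -> MomentSummary:
    """Empirical mRNA/protein moments of a snapshot population."""
    m = snapshot["mrna"].to_numpy(dtype=float)
    p = snapshot["protein"].to_numpy(dtype=float)
    mean_m, mean_p = m.mean(), p.mean()
    var_m = m.var(ddof=1) if len(m) > 1 else 0.0
    var_p = p.var(ddof=1) if len(p) > 1 else 0.0
    return MomentSummary(
        mean_m=mean_m,
        mean_p=mean_p,
        var_m=var_m,
        var_p=var_p,
        cv2_m=var_m / mean_m**2 if mean_m > 0 else float("nan"),
        cv2_p=var_p / mean_p**2 if mean_p > 0 else float("nan"),
        n=len(snapshot),
    )
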