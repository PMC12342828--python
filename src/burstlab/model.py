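"""Two-stage (mRNA-protein) bursty gene-expression model: parameters and
analytic stationary moments.

The kinetic scheme is

    DNA --k_m-->  DNA + G x mRNA      (bursts; G geometric, mean b)
    mRNA --gamma_m--> 0               (first-order degradation)
    mRNA --k_p--> mRNA + protein      (translation)
    protein --gamma_p--> 0            (removal: dilution + partitioning)

At stationarity the mRNA marginal is negative binomial NB(r, p) with
r = k_m/gamma_m and p = 1/(1+b), under the convention
mean = r(1-p)/p, so that the mean burst size is b = (1-p)/p.

The protein noise decomposes into a Poissonian term and an mRNA-driven
(burst) term::

    CV_p^2 = 1/<p> + (1+b)/<m> * gamma_p/(gamma_m + gamma_p)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "MomentSummary",
    "WT_PARAMS",
    "CONDITION_PRESETS",
    "analytic_moments",
    "cv2_theory",
    "cv2_poisson_bound",
    "relaxation_check",
]


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the two-stage bursty model (rates in min^-1).

    Attributes
    ----------
    k_m : burst arrival (transcription) rate.
    b : mean transcriptional burst size, molecules per burst.
    gamma_m : mRNA degradation rate.
    k_p : translation rate per mRNA.
    gamma_p : protein removal rate (dilution-dominated for stable proteins).
    """

    k_m: float
    b: float
    gamma_m: float
    k_p: float
    gamma_p: float

    def __post_init__(self) -> None:
        for name in ("k_m", "b", "gamma_m", "k_p", "gamma_p"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    def with_gene_copies(self, copies: int) -> "ModelParams":
        """Parameters for `copies` independently transcribing gene copies.

        Independent copies superpose their burst arrivals, so only k_m scales.
        """
        if copies not in (1, 2):
            raise ValueError(f"gene copies must be 1 or 2, got {copies}")
        return replace(self, k_m=self.k_m * copies)

    @property
    def nb_r(self) -> float:
        """Shape of the stationary mRNA negative binomial, k_m/gamma_m."""
        self._require_stationary_mrna()
        return self.k_m / self.gamma_m

    @property
    def nb_p(self) -> float:
        """Success probability of the stationary mRNA NB, 1/(1+b)."""
        return 1.0 / (1.0 + self.b)

    def _require_stationary_mrna(self) -> None:
        if self.gamma_m <= 0:
            raise ValueError("stationary moments require gamma_m > 0")

    def _require_stationary(self) -> None:
        self._require_stationary_mrna()
        if self.gamma_p <= 0:
            raise ValueError("stationary moments require gamma_p > 0")


@dataclass(frozen=True)
class MomentSummary:
    """First and second stationary moments of mRNA and protein counts."""

    mean_m: float
    mean_p: float
    var_m: float
    var_p: float
    cv2_m: float
    cv2_p: float
    n: int | None = None


#: Parameters inferred for recB in unperturbed E. coli (newborn regime).
WT_PARAMS = ModelParams(k_m=0.21, b=0.95, gamma_m=0.615, k_p=0.15, gamma_p=0.015)

#: Documented condition presets (parameter changes only, not mechanistic claims):
#: hfq deletion doubles translational efficiency; ciprofloxacin-like DNA damage
#: lowers mRNA output ~2.4-fold and raises translational efficiency ~2.5-fold.
CONDITION_PRESETS: dict[str, ModelParams] = {
    "wt": WT_PARAMS,
    "hfq_del": replace(WT_PARAMS, k_p=WT_PARAMS.k_p * 2.0),
    "cipro": replace(WT_PARAMS, k_m=WT_PARAMS.k_m * 0.42, k_p=WT_PARAMS.k_p * 2.5),
}


def cv2_theory(
    mean_p: float, mean_m: float, b: float, gamma_m: float, gamma_p: float
) -> float:
    """Analytic protein noise CV_p^2 of the two-stage bursty model.

    CV_p^2 = 1/<p> + (1+b)/<m> * gamma_p/(gamma_m+gamma_p): the first term is
    the Poissonian floor of protein birth-death; the second is transmitted
    mRNA (burst) noise, low-pass filtered by the protein lifetime.
    """
    if mean_p <= 0 or mean_m <= 0:
        raise ValueError("means must be positive")
    if gamma_m <= 0 or gamma_p <= 0:
        raise ValueError("decay rates must be positive")
    return 1.0 / mean_p + (1.0 + b) / mean_m * gamma_p / (gamma_m + gamma_p)


def cv2_poisson_bound(mean_m: float) -> float:
    """Poisson lower bound on count noise, 1/<m>."""
    if mean_m <= 0:
        raise ValueError("mean must be positive")
    return 1.0 / mean_m


def analytic_moments(params: ModelParams, gene_copies: int = 1) -> MomentSummary:
    """Stationary moments: <m> = k_m b/gamma_m, <p> = k_p <m>/gamma_p,
    CV_m^2 = (1+b)/<m> (negative binomial), CV_p^2 per :func:`cv2_theory`."""
    p = params.with_gene_copies(gene_copies)
    p._require_stationary()
    mean_m = p.k_m * p.b / p.gamma_m
    mean_p = p.k_p * mean_m / p.gamma_p
    var_m = mean_m * (1.0 + p.b)
    cv2_m = (1.0 + p.b) / mean_m if mean_m > 0 else float("nan")
    if mean_m > 0 and mean_p > 0:
        cv2_p = cv2_theory(mean_p, mean_m, p.b, p.gamma_m, p.gamma_p)
        var_p = cv2_p * mean_p**2
    else:
        cv2_p = float("nan")
        var_p = 0.0
    return MomentSummary(
        mean_m=mean_m, mean_p=mean_p, var_m=var_m, var_p=var_p, cv2_m=cv2_m, cv2_p=cv2_p
    )


def relaxation_check(
    params_before: ModelParams, params_after: ModelParams, t: float
) -> float:
    """Fractional approach of the mean protein level to its new steady state.

    At t = 0 the kinetic parameters switch from `params_before` (system at its
    old steady state) to `params_after`. The mean-field dynamics are linear,

        d<m>/dt = k_m b - gamma_m <m>,   d<p>/dt = k_p <m> - gamma_p <p>,

    with closed-form solution p(t) = p_inf + A e^{-gamma_p t} + B e^{-gamma_m t}
    where B = k_p (m_0 - m_inf)/(gamma_p - gamma_m) and A closes the initial
    condition. Returns (p(t) - p_0)/(p_inf - p_0), in [0, 1); equal degradation
    rates are handled by the degenerate (t e^{-gamma t}) limit.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    before = analytic_moments(params_before)
    after_params = params_after
    after_params._require_stationary()
    after = analytic_moments(after_params)
    m0, p0 = before.mean_m, before.mean_p
    m_inf, p_inf = after.mean_m, after.mean_p
    gm, gp, kp = after_params.gamma_m, after_params.gamma_p, after_params.k_p

    gap = p_inf - p0
    if gap == 0.0:
        return 1.0
    dm = m0 - m_inf
    if math.isclose(gm, gp, rel_tol=1e-12, abs_tol=0.0):
        # degenerate eigenvalues: p(t) = p_inf + e^{-g t} (p0 - p_inf + kp dm t)
        pt = p_inf + math.exp(-gp * t) * (p0 - p_inf + kp * dm * t)
    else:
        b_coef = kp * dm / (gp - gm)
        a_coef = (p0 - p_inf) - b_coef
        pt = p_inf + a_coef * math.exp(-gp * t) + b_coef * math.exp(-gm * t)
    return (pt - p0) / gap
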