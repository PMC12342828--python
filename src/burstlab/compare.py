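"""Distribution and condition comparisons for snapshot populations.

Covers the descriptive statistics used to compare conditions: empirical
Kullback-Leibler divergence between count distributions, pooled two-sample
t-tests on replicate means, size-binned dosage analysis, per-cell
concentrations, translational efficiency (proteins per mRNA), empirical CV^2
and the noise gap CV^2_theory - CV^2_exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MomentSummary

__all__ = [
    "EfficiencyResult",
    "NoiseGapResult",
    "kl_divergence",
    "kl_divergence_pmf",
    "two_sample_ttest",
    "bin_by_size",
    "concentrations",
    "translational_efficiency",
    "cv2_empirical",
    "noise_gap",
]


def kl_divergence_pmf(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(P || Q) in nats for two pmfs on a shared support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("pmfs must share a support")
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise ValueError("Q must be positive wherever P is")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_divergence(p_counts, q_counts, pseudo_count: float = 0.5) -> float:
    """D_KL between two empirical count distributions, in nats.

    Both samples are histogrammed on the union support {0..max}; a pseudo
    count (default 0.5) is added to every bin before normalization so that
    the divergence is finite when one sample misses a count value. The
    divergence is asymmetric: the first argument plays the role of the
    reference (e.g. simulated) distribution.
    """
    p_counts = np.asarray(p_counts)
    q_counts = np.asarray(q_counts)
    if len(p_counts) == 0 or len(q_counts) == 0:
        raise ValueError("both samples must be non-empty")
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be >= 0")
    kmax = int(max(p_counts.max(), q_counts.max()))
    support = np.arange(kmax + 2)
    p_hist = np.bincount(p_counts.astype(int), minlength=len(support)).astype(float)
    q_hist = np.bincount(q_counts.astype(int), minlength=len(support)).astype(float)
    p_hist += pseudo_count
    q_hist += pseudo_count
    return kl_divergence_pmf(p_hist / p_hist.sum(), q_hist / q_hist.sum())


def two_sample_ttest(x, y) -> tuple[float, float]:
    """Pooled (equal-variance) two-sample t-test; returns (t, two-sided p).

    Degenerate inputs follow the conventions: zero pooled variance with equal
    means gives (0, 1); zero variance with unequal means gives (+-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def bin_by_size(
    snapshot: pd.DataFrame, bin_edges, value: str = "mrna"
) -> pd.DataFrame:
    """Bin a per-cell quantity by cell area: mean +- sem per bin, plus a
    three-bin centered moving average of the means.

    Empty bins are reported with n = 0 and NaN mean and are skipped by the
    moving average; edge bins average over the neighbours that exist.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    areas = snapshot["area_um2"].to_numpy(dtype=float)
    vals = snapshot[value].to_numpy(dtype=float)
    idx = np.digitize(areas, edges) - 1
    rows = []
    for i in range(len(edges) - 1):
        sel = vals[idx == i]
        n = len(sel)
        mean = sel.mean() if n else np.nan
        sem = sel.std(ddof=1) / np.sqrt(n) if n > 1 else (0.0 if n == 1 else np.nan)
        rows.append(
            {
                "bin_left": edges[i],
                "bin_right": edges[i + 1],
                "bin_center": 0.5 * (edges[i] + edges[i + 1]),
                "n": n,
                "mean": mean,
                "sem": sem,
            }
        )
    out = pd.DataFrame(rows)
    means = out["mean"].to_numpy()
    occupied = np.flatnonzero(out["n"].to_numpy() > 0)
    moving = np.full(len(out), np.nan)
    for j, i in enumerate(occupied):
        neighbours = occupied[max(0, j - 1) : j + 2]
        moving[i] = means[neighbours].mean()
    out["moving_average"] = moving
    return out


def concentrations(snapshot: pd.DataFrame) -> pd.DataFrame:
    """Per-cell molecule concentrations (molecules/um^2)."""
    areas = snapshot["area_um2"].to_numpy(dtype=float)
    if np.any(areas <= 0):
        raise ValueError("cell areas must be positive")
    out = snapshot.copy()
    out["mrna_conc"] = out["mrna"] / areas
    out["protein_conc"] = out["protein"] / areas
    return out


@dataclass(frozen=True)
class EfficiencyResult:
    """Translational efficiency: mean protein concentration per mean mRNA
    concentration (proteins per mRNA), with the spread across replicates."""

    c_p: float
    c_m: float
    efficiency: float
    spread: float
    n_replicates: int


def translational_efficiency(
    c_p_replicates, c_m_replicates, pooled: bool = False
) -> EfficiencyResult:
    """Efficiency = mean(c_p)/mean(c_m) across replicate mean concentrations.

    With ``pooled=True`` the inputs are interpreted as pooled per-cell
    concentrations instead of replicate means (same arithmetic, no replicate
    spread).
    """
    cp = np.asarray(c_p_replicates, dtype=float)
    cm = np.asarray(c_m_replicates, dtype=float)
    if len(cp) == 0 or len(cm) == 0:
        raise ValueError("need at least one replicate")
    if cm.mean() <= 0 or np.any(cm <= 0):
        raise ValueError("mRNA concentrations must be positive")
    eff = cp.mean() / cm.mean()
    if pooled or len(cp) != len(cm) or len(cp) < 2:
        spread = 0.0
    else:
        spread = float(np.std(cp / cm, ddof=1))
    return EfficiencyResult(
        c_p=float(cp.mean()),
        c_m=float(cm.mean()),
        efficiency=float(eff),
        spread=spread,
        n_replicates=int(len(cp)),
    )


def cv2_empirical(counts) -> tuple[float, MomentSummary]:
    """Empirical noise: sample variance over squared sample mean."""
    x = np.asarray(counts, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean must be positive for CV^2")
    var = x.var(ddof=1) if len(x) > 1 else 0.0
    cv2 = var / mean**2
    summary = MomentSummary(
        mean_m=mean, mean_p=float("nan"), var_m=var, var_p=float("nan"),
        cv2_m=cv2, cv2_p=float("nan"), n=len(x),
    )
    return float(cv2), summary


@dataclass(frozen=True)
class NoiseGapResult:
    """Noise suppression measure: CV^2_theory - mean(CV^2_exp)."""

    cv2_theory: float
    cv2_exp: tuple[float, ...]
    gap: float
    sem: float


def noise_gap(cv2_theory_value: float, cv2_exp_replicates) -> NoiseGapResult:
    """Gap between predicted and measured protein noise, with SEM across
    replicates (0 for a single replicate)."""
    reps = np.asarray(cv2_exp_replicates, dtype=float)
    if len(reps) == 0:
        raise ValueError("need at least one replicate")
    gap = float(cv2_theory_value - reps.mean())
    sem = float(reps.std(ddof=1) / np.sqrt(len(reps))) if len(reps) > 1 else 0.0
    return NoiseGapResult(
        cv2_theory=float(cv2_theory_value),
        cv2_exp=tuple(float(r) for r in reps),
        gap=gap,
        sem=sem,
    )
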