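"""Exact stochastic simulation (Gillespie SSA) of the two-stage bursty model.

Reactions and propensities:

====================  =================  ==========================
event                 propensity         state change
====================  =================  ==========================
transcription burst   k_m                m += G, G ~ Geometric0(1/(1+b))
mRNA degradation      gamma_m * m        m -= 1
translation           k_p * m            p += 1
protein removal       gamma_p * p        p -= 1
====================  =================  ==========================

Geometric0 is the geometric law on {0, 1, 2, ...} with mean b, sampled by
inverse CDF. The constitutive limit (`constitutive=True`) replaces G by
exactly 1 molecule per arrival, giving a Poisson stationary mRNA marginal.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from .model import ModelParams

__all__ = ["Trajectory", "EnsembleSnapshot", "ssa_trajectory", "steady_state_ensemble"]


@dataclass(frozen=True)
class Trajectory:
    """A single SSA sample path; states are aligned to event times."""

    event_times: np.ndarray
    mrna_path: np.ndarray
    protein_path: np.ndarray


@dataclass(frozen=True)
class EnsembleSnapshot:
    """Independent (mrna, protein) samples taken at t = burn_in per run."""

    mrna: np.ndarray
    protein: np.ndarray
    n_runs: int
    burn_in: float
    seed: int


def _sample_burst(rnd: random.Random, log1m_q: float) -> int:
    # inverse CDF of Geometric0(q): G = floor(ln U / ln(1-q))
    if log1m_q == 0.0:  # b == 0: every burst is empty
        return 0
    return int(math.log(rnd.random()) / log1m_q)


def _advance(
    params: ModelParams,
    t_end: float,
    rnd: random.Random,
    m: int,
    p: int,
    constitutive: bool,
    record: list | None = None,
) -> tuple[int, int]:
    """Run the SSA from state (m, p) until t_end; optionally record events."""
    km, b, gm, kp, gp = params.k_m, params.b, params.gamma_m, params.k_p, params.gamma_p
    log1m_q = math.log1p(-1.0 / (1.0 + b)) if b > 0 else 0.0
    t = 0.0
    exp = rnd.expovariate
    uni = rnd.random
    while True:
        a1 = km
        a2 = gm * m
        a3 = kp * m
        a4 = gp * p
        total = a1 + a2 + a3 + a4
        if total == 0.0:
            break
        t += exp(total)
        if t >= t_end:
            break
        u = uni() * total
        if u < a1:
            m += 1 if constitutive else _sample_burst(rnd, log1m_q)
        elif u < a1 + a2:
            m -= 1
        elif u < a1 + a2 + a3:
            p += 1
        else:
            p -= 1
        if record is not None:
            record.append((t, m, p))
    return m, p


def ssa_trajectory(
    params: ModelParams,
    t_end: float,
    seed: int,
    init: tuple[int, int] = (0, 0),
    constitutive: bool = False,
) -> Trajectory:
    """Simulate one exact sample path of the two-stage model.

    Parameters
    ----------
    params : kinetic parameters (rates >= 0).
    t_end : simulation horizon in minutes.
    seed : RNG seed; identical seeds reproduce identical paths.
    init : initial (mrna, protein) counts.
    constitutive : if True, every burst delivers exactly one mRNA.
    """
    if t_end <= 0 or not math.isfinite(t_end):
        raise ValueError("t_end must be positive and finite")
    m0, p0 = init
    if m0 < 0 or p0 < 0:
        raise ValueError("initial counts must be non-negative")
    rnd = random.Random(seed)
    record: list[tuple[float, int, int]] = [(0.0, m0, p0)]
    _advance(params, t_end, rnd, m0, p0, constitutive, record)
    arr = np.asarray(record, dtype=float)
    return Trajectory(
        event_times=arr[:, 0],
        mrna_path=arr[:, 1].astype(np.int64),
        protein_path=arr[:, 2].astype(np.int64),
    )


def steady_state_ensemble(
    params: ModelParams,
    n_runs: int = 10_000,
    burn_in: float | None = None,
    seed: int = 0,
    init: tuple[int, int] = (0, 0),
    constitutive: bool = False,
) -> EnsembleSnapshot:
    """Sample the stationary joint (mRNA, protein) law by independent SSA runs.

    Each run starts from `init`, evolves for `burn_in` minutes with its own
    seeded stream (derived deterministically from `seed`), and contributes one
    snapshot. The default burn-in is 10/gamma_p, ten times the slowest
    relaxation timescale; a warning is emitted below 5/gamma_p.
    """
    if n_runs <= 0:
        raise ValueError("n_runs must be positive")
    # slowest timescale that matters: the protein stage only if it is active
    protein_active = params.k_p > 0 or init[1] > 0
    slow_rate = params.gamma_p if protein_active else params.gamma_m
    if burn_in is None:
        if slow_rate <= 0:
            raise ValueError("automatic burn-in requires a positive decay rate")
        burn_in = 10.0 / slow_rate
    if slow_rate > 0 and burn_in < 5.0 / slow_rate:
        import warnings

        warnings.warn(
            f"burn_in={burn_in:g} min is below 5x the slowest relaxation time "
            f"({5.0 / slow_rate:g} min); the ensemble may not be stationary",
            stacklevel=2,
        )
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    mrna = np.empty(n_runs, dtype=np.int64)
    protein = np.empty(n_runs, dtype=np.int64)
    for i in range(n_runs):
        rnd = random.Random(int(run_seeds[i]))
        m, p = _advance(params, burn_in, rnd, init[0], init[1], constitutive)
        mrna[i] = m
        protein[i] = p
    return EnsembleSnapshot(
        mrna=mrna, protein=protein, n_runs=n_runs, burn_in=float(burn_in), seed=seed
    )
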