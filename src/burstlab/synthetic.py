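"""Seeded synthetic datasets with the statistical structure of single-molecule
snapshot and time-course experiments.

This module emulates what smFISH / Halo-labelling experiments provide:

* population snapshots — one row per cell with area (um^2), gene copy state,
  and integer mRNA and protein counts drawn from the stationary two-stage
  bursty model (SSA burn-in, or exact NB sampling when the protein stage is
  off);
* decay time courses — mean counts after blocking transcription (rifampicin)
  or after removing the labelling dye (pulse-chase), with per-timepoint
  sampling noise from finite cell numbers;
* spot-intensity samples — the one-vs-two-transcript intensity mixture used
  to calibrate the one-mRNA intensity equivalent;
* rendered spot fields — 2D images of Gaussian-profile spots over a labelled
  cell mask, with ground truth, for testing the detection pipeline.

Gene dosage is modelled as a sharp duplication above a configurable cell-area
threshold, with the two copies transcribing independently (k_m doubles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CONDITION_PRESETS, ModelParams
from .ssa import _advance

__all__ = [
    "PopulationConfig",
    "CellRecord",
    "TimeCourse",
    "SpotIntensitySample",
    "make_population",
    "make_decay_timecourse",
    "make_pulse_chase",
    "sample_spot_intensities",
    "render_spot_field",
    "standard_spot_field",
]

SNAPSHOT_COLUMNS = [
    "cell_id",
    "area_um2",
    "gene_copies",
    "mrna",
    "protein",
    "condition",
    "replicate",
]


@dataclass(frozen=True)
class CellRecord:
    """A single cell: area, gene-copy state and integer molecule counts."""

    cell_id: str
    area: float
    gene_copies: int
    mrna: int
    protein: int

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.gene_copies not in (1, 2):
            raise ValueError("gene_copies must be 1 or 2")
        if self.mrna < 0 or self.protein < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of a snapshot population.

    Cell areas follow a lognormal law with the given median (um^2); cells at
    or above `dosage_threshold` carry a duplicated gene (2x burst arrival
    rate). `area_sigma` is the SD of log-area. `newborns_only` truncates the
    area law below the newborn threshold so that the non-growing steady-state
    model applies to every cell.
    """

    params: ModelParams = field(default_factory=lambda: CONDITION_PRESETS["wt"])
    n_cells: int = 1000
    area_median: float = 1.9
    area_sigma: float = 0.35
    dosage_threshold: float = 3.25
    newborns_only: bool = False
    newborn_area_max: float = 3.0
    condition_label: str = "wt"
    seed: int = 0
    replicate_id: int = 1
    burn_in: float | None = None  # default 5/gamma_p (or 5/gamma_m if k_p = 0)
    method: str = "auto"  # "ssa" | "exact" | "auto"

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.dosage_threshold <= 0:
            raise ValueError("dosage_threshold must be positive")
        if self.area_median <= 0 or self.area_sigma <= 0:
            raise ValueError("area law parameters must be positive")
        if self.method not in ("auto", "ssa", "exact"):
            raise ValueError(f"unknown method {self.method!r}")


def _sample_areas(config: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    mu = math.log(config.area_median)
    if not config.newborns_only:
        return rng.lognormal(mu, config.area_sigma, size=config.n_cells)
    # rejection sampling of the truncated lognormal below the newborn cut
    areas = np.empty(config.n_cells)
    filled = 0
    while filled < config.n_cells:
        draw = rng.lognormal(mu, config.area_sigma, size=2 * config.n_cells)
        draw = draw[draw < config.newborn_area_max]
        take = min(len(draw), config.n_cells - filled)
        areas[filled : filled + take] = draw[:take]
        filled += take
    return areas


def make_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw a snapshot population from the stationary two-stage model.

    Returns a DataFrame with columns ``cell_id, area_um2, gene_copies, mrna,
    protein, condition, replicate``. Counts are drawn per cell from the
    stationary law at that cell's gene dosage: by SSA burn-in, or — when the
    protein stage is off (k_p = 0) — by exact negative-binomial sampling of
    the mRNA marginal. Identical (config, seed) gives identical output.
    """
    params = config.params
    stationary_needed = config.method != "ssa" or config.burn_in is None
    if stationary_needed and params.gamma_m <= 0:
        raise ValueError("stationary snapshot requires gamma_m > 0")
    if params.k_p > 0 and params.gamma_p <= 0 and config.burn_in is None:
        raise ValueError("stationary snapshot requires gamma_p > 0 when k_p > 0")

    method = config.method
    if method == "auto":
        method = "exact" if params.k_p == 0 else "ssa"
    if method == "exact" and params.k_p != 0:
        raise ValueError("exact sampling is only available for k_p = 0")

    rng = np.random.default_rng(config.seed)
    areas = _sample_areas(config, rng)
    copies = np.where(areas >= config.dosage_threshold, 2, 1)

    mrna = np.empty(config.n_cells, dtype=np.int64)
    protein = np.zeros(config.n_cells, dtype=np.int64)
    if method == "exact":
        for c in (1, 2):
            idx = copies == c
            if idx.any():
                r = c * params.k_m / params.gamma_m
                if r == 0:
                    mrna[idx] = 0
                else:
                    mrna[idx] = rng.negative_binomial(r, params.nb_p, size=idx.sum())
    else:
        slow = params.gamma_p if params.k_p > 0 else params.gamma_m
        burn_in = config.burn_in if config.burn_in is not None else 5.0 / slow
        import random as _random

        cell_seeds = np.random.SeedSequence(config.seed).generate_state(
            config.n_cells, dtype=np.uint64
        )
        for i in range(config.n_cells):
            cell_params = params.with_gene_copies(int(copies[i]))
            rnd = _random.Random(int(cell_seeds[i]))
            m, p = _advance(cell_params, burn_in, rnd, 0, 0, False)
            mrna[i] = m
            protein[i] = p

    return pd.DataFrame(
        {
            "cell_id": [f"{config.condition_label}_r{config.replicate_id}_c{i:06d}"
                        for i in range(config.n_cells)],
            "area_um2": areas,
            "gene_copies": copies,
            "mrna": mrna,
            "protein": protein,
            "condition": config.condition_label,
            "replicate": config.replicate_id,
        }
    )


@dataclass(frozen=True)
class TimeCourse:
    """Mean molecule counts over time for a decay experiment."""

    times: np.ndarray
    mean_counts: np.ndarray
    n_cells_per_timepoint: np.ndarray
    normalization_anchor: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("times must be a 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.asarray(self.mean_counts) < 0):
            raise ValueError("mean counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "mean_count": self.mean_counts,
                "n_cells": self.n_cells_per_timepoint,
            }
        )


def _require_t0(times: np.ndarray) -> None:
    if not np.any(np.isclose(times, 0.0)):
        raise ValueError("times must include t = 0 (normalization anchor)")


def make_decay_timecourse(
    params: ModelParams,
    times,
    n_cells_per_timepoint: int | None = 3000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeCourse:
    """Rifampicin-like mRNA decay series: means follow M0 exp(-gamma_m t).

    After transcription stops, each stationary NB-distributed cell count is
    binomially thinned with survival exp(-gamma_m t); thinning a negative
    binomial rescales its mean at fixed shape, so per-timepoint counts are
    drawn exactly from NB(r, p_t) with mean M0 exp(-gamma_m t). With
    ``n_cells_per_timepoint=None`` the series is noiseless. `noise_sd` adds
    Gaussian measurement error to the means.
    """
    times = np.asarray(times, dtype=float)
    _require_t0(times)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if params.gamma_m <= 0:
        raise ValueError("decay time course requires gamma_m > 0")
    r = params.k_m / params.gamma_m
    m0 = params.k_m * params.b / params.gamma_m
    target_means = m0 * np.exp(-params.gamma_m * times)
    rng = np.random.default_rng(seed)
    if n_cells_per_timepoint is None:
        means = target_means.copy()
        n_arr = np.zeros(len(times), dtype=np.int64)
    else:
        if n_cells_per_timepoint <= 0:
            raise ValueError("n_cells_per_timepoint must be positive")
        means = np.empty(len(times))
        for i, mean_t in enumerate(target_means):
            p_t = r / (r + mean_t) if mean_t > 0 else 1.0
            counts = rng.negative_binomial(r, p_t, size=n_cells_per_timepoint)
            means[i] = counts.mean()
        n_arr = np.full(len(times), n_cells_per_timepoint, dtype=np.int64)
    if noise_sd > 0:
        means = np.clip(means + rng.normal(0.0, noise_sd, size=len(means)), 0.0, None)
    anchor = int(np.argmin(np.abs(times)))
    return TimeCourse(times, means, n_arr, normalization_anchor=anchor)


def make_pulse_chase(
    params: ModelParams,
    times,
    n_cells_per_timepoint: int | None = 500,
    noise_sd: float = 0.0,
    seed: int = 0,
    removal_rate: float | None = None,
) -> TimeCourse:
    """Pulse-chase protein decay series: labelled molecules only decay.

    A stationary protein ensemble is sampled once by SSA; at each timepoint
    every labelled molecule independently survives with probability
    exp(-rate * t) (binomial thinning). `removal_rate` overrides gamma_p,
    e.g. to compare against a dilution-only rate.
    """
    times = np.asarray(times, dtype=float)
    _require_t0(times)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rate = params.gamma_p if removal_rate is None else removal_rate
    if rate <= 0:
        raise ValueError("protein removal rate must be positive")
    rng = np.random.default_rng(seed)
    if n_cells_per_timepoint is None:
        from .model import analytic_moments

        p0 = analytic_moments(params).mean_p
        means = p0 * np.exp(-rate * times)
        n_arr = np.zeros(len(times), dtype=np.int64)
    else:
        if n_cells_per_timepoint <= 0:
            raise ValueError("n_cells_per_timepoint must be positive")
        from .ssa import steady_state_ensemble

        base = steady_state_ensemble(
            params, n_runs=n_cells_per_timepoint, seed=int(rng.integers(2**31))
        ).protein
        means = np.empty(len(times))
        for i, t in enumerate(times):
            surv = math.exp(-rate * t)
            means[i] = rng.binomial(base, surv).mean()
        n_arr = np.full(len(times), n_cells_per_timepoint, dtype=np.int64)
    if noise_sd > 0:
        means = np.clip(means + rng.normal(0.0, noise_sd, size=len(means)), 0.0, None)
    anchor = int(np.argmin(np.abs(times)))
    return TimeCourse(times, means, n_arr, normalization_anchor=anchor)


@dataclass(frozen=True)
class SpotIntensitySample:
    """Integrated spot intensities with ground-truth multiplicity (1 or 2)."""

    intensities: np.ndarray
    true_multiplicity: np.ndarray


def sample_spot_intensities(
    b_i: float,
    c: float,
    frac_doublets: float = 0.2,
    n: int = 5000,
    seed: int = 0,
) -> SpotIntensitySample:
    """Sample the one-vs-two-transcript intensity mixture.

    Singlets ~ N(b_i, c^2/2); doublets ~ N(2 b_i, c^2): two independent
    probe-binding processes give twice the mean and twice the variance.
    Negative draws are rejected and resampled.
    """
    if b_i <= 0 or c <= 0:
        raise ValueError("b_i and c must be positive")
    if not 0.0 <= frac_doublets <= 1.0:
        raise ValueError("frac_doublets must be in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    mult = np.where(rng.random(n) < frac_doublets, 2, 1)
    means = np.where(mult == 2, 2.0 * b_i, b_i)
    sds = np.where(mult == 2, c, c / math.sqrt(2.0))
    intensities = rng.normal(means, sds)
    bad = intensities <= 0
    while bad.any():
        intensities[bad] = rng.normal(means[bad], sds[bad])
        bad = intensities <= 0
    return SpotIntensitySample(intensities=intensities, true_multiplicity=mult)


def _ellipse_mask(shape, cx, cy, rx, ry):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def render_spot_field(
    cells,
    spots,
    shape: tuple[int, int] = (256, 256),
    psf_sigma_px: float = 1.3,
    background: float = 100.0,
    noise_sd: float = 10.0,
    seed: int = 0,
):
    """Render a 2D spot field over a labelled cell mask.

    Parameters
    ----------
    cells : sequence of (cx, cy, rx, ry) ellipse cell outlines (pixels);
        labels 1..len(cells) in the returned mask.
    spots : sequence of (x, y, integrated_intensity); the Gaussian profile of
        each spot is normalized so that its pixel sum equals the requested
        integrated intensity.
    shape : image (height, width).

    Returns
    -------
    image : float64 array, background + spots + Gaussian read noise.
    truth : DataFrame (x, y, intensity, cell_id) with cell_id from the mask
        at the spot's rounded pixel (0 = outside all cells).
    mask : uint16 label image.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    h, w = shape
    mask = np.zeros(shape, dtype=np.uint16)
    for label, (cx, cy, rx, ry) in enumerate(cells, start=1):
        mask[_ellipse_mask(shape, cx, cy, rx, ry)] = label
    image = np.full(shape, float(background))
    yy, xx = np.mgrid[0:h, 0:w]
    records = []
    norm = 2.0 * math.pi * psf_sigma_px**2
    for x, y, intensity in spots:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"spot ({x}, {y}) outside image bounds {shape}")
        image += (
            intensity
            / norm
            * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * psf_sigma_px**2))
        )
        records.append(
            {
                "x": float(x),
                "y": float(y),
                "intensity": float(intensity),
                "cell_id": int(mask[int(round(y)), int(round(x))]),
            }
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image += rng.normal(0.0, noise_sd, size=shape)
    truth = pd.DataFrame(records, columns=["x", "y", "intensity", "cell_id"])
    return image, truth, mask


def standard_spot_field(
    seed: int = 0,
    n_cells: int = 9,
    spots_per_cell=(0, 6),
    snr: float = 10.0,
    psf_sigma_px: float = 1.3,
    background: float = 100.0,
    noise_sd: float = 10.0,
    shape: tuple[int, int] = (192, 192),
):
    """The standard detection fixture: a grid of elliptical cells with
    well-spread spots at the requested peak signal-to-noise ratio.

    Peak amplitude = snr * noise_sd, so the integrated intensity per spot is
    snr * noise_sd * 2 pi sigma^2. Spot density stays below ~0.02 /px^2.
    """
    rng = np.random.default_rng(seed)
    side = int(math.ceil(math.sqrt(n_cells)))
    h, w = shape
    pitch_y, pitch_x = h / side, w / side
    cells = []
    for i in range(n_cells):
        cy = (i // side + 0.5) * pitch_y
        cx = (i % side + 0.5) * pitch_x
        cells.append((cx, cy, 0.42 * pitch_x, 0.42 * pitch_y))
    intensity = snr * noise_sd * 2.0 * math.pi * psf_sigma_px**2
    spots = []
    lo, hi = spots_per_cell
    for cx, cy, rx, ry in cells:
        k = int(rng.integers(lo, hi + 1))
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < k and attempts < 200:
            attempts += 1
            ang = rng.uniform(0, 2 * math.pi)
            rad = math.sqrt(rng.uniform(0, 1))
            x = cx + 0.85 * rx * rad * math.cos(ang)
            y = cy + 0.85 * ry * rad * math.sin(ang)
            if all((x - px) ** 2 + (y - py) ** 2 > 8.0**2 for px, py in placed):
                placed.append((x, y))
        spots.extend((x, y, intensity) for x, y in placed)
    return render_spot_field(
        cells,
        spots,
        shape=shape,
        psf_sigma_px=psf_sigma_px,
        background=background,
        noise_sd=noise_sd,
        seed=seed + 1,
    )
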