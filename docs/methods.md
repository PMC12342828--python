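# Methods

## The two-stage bursty expression model

All inference in `burstlab` is organized around the two-stage (mRNA–protein)
model of gene expression with bursty transcription. Transcription bursts
arrive as a Poisson process at rate `k_m` (min⁻¹); each burst instantaneously
adds `G` mRNAs, where `G` is geometric on {0, 1, 2, …} with mean `b`
(success parameter `q = 1/(1+b)`). mRNAs decay at `gamma_m` per molecule,
are translated at `k_p` per molecule, and proteins are removed at `gamma_p`
per molecule. Protein removal lumps dilution by growth and partitioning at
division into a single first-order reaction; the model has no explicit cell
cycle, which is why distribution-level inference is restricted to *newborn*
cells (smallest area class), where the non-growing steady-state assumption
is least wrong.

Under this burst law the stationary mRNA marginal is negative binomial
NB(`r`, `p`) with `r = k_m/gamma_m` and `p = 1/(1+b)`. We use the convention
`⟨m⟩ = r(1−p)/p` throughout (the `scipy.stats.nbinom` convention). This is a
deliberate choice: it is the unique convention under which the burst-size
relation `b = (1−p)/p`, the transcription-rate relation `k_m = gamma_m·r`
and the observed newborn mean count are mutually consistent; the reciprocal
convention (`⟨m⟩ = pr/(1−p)`) is inconsistent with those relations and is
not used anywhere in the package.

Stationary moments: `⟨m⟩ = k_m·b/gamma_m`, `⟨p⟩ = k_p·⟨m⟩/gamma_p`,
mRNA Fano factor `1+b`, and the protein noise decomposition

```
CV_p² = 1/⟨p⟩ + (1+b)/⟨m⟩ · gamma_p/(gamma_m + gamma_p)
```

whose first term is the Poissonian floor of protein birth–death and whose
second is transmitted mRNA/burst noise low-pass filtered by the protein
lifetime. `CV_p²` can never fall below `1/⟨p⟩` (property-tested); measured
noise falling below the full prediction is the operational definition of
noise suppression (the "noise gap").

### Relaxation after a parameter shift

To check whether a treatment duration suffices to reach a new steady state,
the mean-field equations (linear ODEs for `⟨m⟩`, `⟨p⟩`) are solved in closed
form after an instantaneous parameter switch; `relaxation_check` returns the
fraction of the protein-mean gap closed at time `t`. The degenerate case
`gamma_m = gamma_p` uses the `t·e^{−γt}` limiting form. The closed form is
validated in tests against `scipy.integrate.solve_ivp` to 1e-8.

## Stochastic simulation

`ssa_trajectory` / `steady_state_ensemble` implement the exact Gillespie
algorithm for the four reactions above. Burst sizes are drawn by inverse CDF
of the geometric law; a `constitutive=True` flag replaces bursts by single
molecules, giving the Poisson limit used as an internal control (Fano
factor 1). Ensembles use one independently seeded stream per run, derived
deterministically from a master seed via `numpy.random.SeedSequence`, so
results are fully reproducible and runs are exchangeable.

Burn-in defaults to `10/gamma_p` (ten times the slowest relaxation time;
`10/gamma_m` when the protein stage is inactive), twice the `5/γ` minimum at
which residual initial-condition bias is ~e⁻⁵; a warning is emitted below
the minimum. Simulator correctness is cross-checked three ways: the
stationary mRNA marginal against the analytic NB law (chi-square at
n = 10,000), protein mean/variance against the analytic moments for burst
sizes spanning 0.1–10, and short-horizon dynamics against an independent
fine-step tau-leaping integrator.

## Synthetic data generator

The generator produces datasets with the statistical structure the analysis
assumes, not microscope-realistic data.

- **Populations**: per-cell areas are lognormal (median 1.9 µm² untreated,
  3.6 µm² for the DNA-damage-like preset — the reported medians; the
  log-SD 0.35 is our choice, giving a realistic ~2.8-fold interquartile-ish
  spread since only medians are reported). Gene dosage is a sharp
  duplication at 3.25 µm² (midpoint of the observed 3.0–3.5 µm² transition),
  with both copies transcribing independently (`k_m` doubles). Counts are
  drawn per cell by SSA burn-in, or exactly from the NB marginal when
  `k_p = 0` (used for large-n mRNA-only studies).
- **Decay time courses**: after transcription stops, each molecule survives
  independently, so a stationary NB count thinned binomially remains NB with
  rescaled mean; per-timepoint means are therefore sampled exactly at finite
  cell number (default 3,000 cells/timepoint, matching experiment-scale
  sampling noise). Pulse-chase series thin a stationary SSA protein
  ensemble the same way. `n_cells_per_timepoint=None` gives noiseless
  series for exactness tests.
- **Spot intensities**: singlets N(b_I, c²/2), doublets N(2·b_I, c²) —
  two independent probe-binding processes give twice the mean and twice the
  variance — with negative draws rejected.
- **Spot fields**: Gaussian-profile spots (normalized so the pixel sum
  equals the requested integrated intensity) over elliptical label masks,
  plus white Gaussian read noise. No optical aberrations, EM-gain noise
  statistics, z-stacks or cell-to-cell background structure are modelled, so
  passing detection tests demonstrates algorithmic correctness on idealized
  images, not performance on real micrographs.

Condition presets (`hfq_del`: 2× `k_p`; `cipro`: 0.42× `k_m`, 2.5× `k_p`)
encode the reported fold-changes as documentation-level defaults; they are
parameter bookkeeping, not mechanistic claims.

## Estimation procedures and numerical choices

- **NB MLE** (`NegativeBinomialEstimator`): raw-count likelihood maximized
  over `(log r, logit p)` by L-BFGS-B from the moment estimator start. The
  unconstrained parametrization keeps the optimizer inside the valid domain;
  a grid-search likelihood oracle (10⁻³ resolution) guards against local
  optima in tests. Under-dispersed samples are rejected with an explicit
  error naming the Poisson boundary, where `r → ∞` and the fit is
  unidentifiable. At a 2,180-cell sample and the inferred parameter point,
  the sampling SD of `r̂` is ≈ 0.04, which bounds what any estimator can
  promise per seed.
- **Decay fits**: means normalized to t = 0 (making the fit scale
  invariant), natural log, OLS; `gamma = −slope`, CI from the slope SE with
  a t quantile. When no window is given, a documented heuristic refits after
  dropping points whose residual from a preliminary full fit exceeds 2 SD.
  Timepoint (horizontal) uncertainty is ignored — standard OLS — and is a
  stated limitation. Replicate pooling averages rates and takes the wider
  of (mean replicate CI half-width, t-based half-width of the replicate
  spread), since the two notions of replicate uncertainty need not coincide; the
  wider one is conservative either way.
- **Intensity mixture**: least squares of
  `a·exp(−(x−b)²/c²) + d·exp(−(x−2b)²/(2c²))` on a Freedman–Diaconis
  density histogram. Initialization: `b` at the histogram mode, `c` at twice
  the SD of the lower half-sample, with 5 log-normally jittered restarts and
  lowest-residual tie-break. Fitting the histogram (rather than a sample
  MLE) mirrors the standard practice for this calibration.
- **Spot detection**: candidates from `skimage.feature.peak_local_max` on
  the raw or inverted-LoG image; 2D Gaussian refinement (amplitude, center,
  sigma, offset) by `curve_fit` in an odd window (default 7 px); local
  background = median of the window border; integrated intensity =
  background-subtracted window sum; candidates within 2 px of an accepted
  brighter spot are deduplicated; fit failures are dropped with a logged
  warning. Peak-height and maxima thresholds are exposed as configuration
  with defaults chosen on the synthetic fixtures (real experiments choose
  them per dataset from intensity profiles). Multiplicity =
  `max(1, round(I/b_I))`; Halo (protein) images skip calibration and count
  each accepted spot once.
- **KL divergence**: empirical pmfs on the union support with a 0.5
  pseudo-count per bin before normalization (keeps D_KL finite on disjoint
  supports); natural-log units; asymmetric with the first argument as the
  reference distribution.
- **t-test**: pooled equal-variance two-sample variant (the classical
  textbook default, not Welch), with explicit conventions for
  degenerate zero-variance inputs.

## Problem sizes

Default problem sizes were chosen so every statistical claim is resolved
with margin: 10,000–60,000 SSA runs for stationary ensembles (Monte-Carlo SE
of the mRNA mean ≤ 0.008 at 10,000), 50,000 cells for dosage-doubling checks
(exact NB path), 100 seeded repetitions for CI-coverage studies, 5,000
spots for calibration recovery. The acceptance script uses 60,000 SSA runs.

## Known limitations

- No cell-cycle/lineage structure: dosage is a static area threshold, and
  removal is memoryless; age-structured effects on the count distributions
  are not represented.
- Detection is 2D single-plane; real multi-plane stacks must be reduced
  before analysis.
- The intensity mixture models at most two co-localized transcripts; higher
  multiplicities are handled only through rounding of normalized intensity.
- The synthetic generator's noise realism is limited (white Gaussian read
  noise, ideal PSF), so detection thresholds tuned on fixtures will not
  transfer to real images unchanged.
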