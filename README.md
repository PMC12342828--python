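# burstlab

Single-molecule quantification and stochastic modelling of bursty gene
expression in bacteria.

Many bacterial proteins — DNA-repair enzymes among them — are present at just
a handful of copies per cell. At such low abundance, transcription in rare
bursts should make protein numbers highly variable from cell to cell, and a
smaller-than-predicted variability is the signature of a regulatory mechanism
(for example, a post-transcriptional repressor) suppressing fluctuations.
`burstlab` provides the full analysis chain needed to make that argument
quantitative from single-molecule snapshot data (smFISH mRNA counts,
Halo-labelling protein counts):

- **spot analysis** — detection of diffraction-limited spots (local maxima +
  2D Gaussian refinement), calibration of integrated intensity to mRNA
  equivalents with a constrained two-Gaussian mixture, and per-cell counting
  against segmentation masks;
- **rate estimation** — first-order removal rates from rifampicin and
  pulse-chase time courses (log-linear OLS with t-based CIs) and growth rates
  from OD series;
- **expression inference** — maximum-likelihood negative-binomial fits to
  newborn-conditioned mRNA counts, giving the burst size and transcription
  rate, plus the moment-matched translation rate;
- **a Gillespie simulator** of the two-stage bursty model and its analytic
  moments;
- **comparison statistics** — KL divergence, size-binned gene-dosage curves,
  concentrations, translational efficiency, empirical CV² and the noise gap;
- **a synthetic-data generator** that emulates the statistical structure of
  the experiments, so the whole pipeline is testable without any raw data.

## The model

The two-stage (mRNA–protein) model with bursty transcription: bursts arrive
at rate $k_m$, each adding a geometric number of mRNAs with mean $b$; mRNAs
decay at $\gamma_m$, are translated at $k_p$, and proteins are removed at
$\gamma_p$. At steady state the mRNA marginal is negative binomial
$\mathrm{NB}(r, p)$ with $r = k_m/\gamma_m$ and $p = 1/(1+b)$ (convention
$\langle m\rangle = r(1-p)/p$), so an MLE fit of the newborn-cell mRNA
distribution yields

$$b = \frac{1-p}{p}, \qquad k_m = \gamma_m r, \qquad
  k_p = \frac{\gamma_p \langle p\rangle}{\langle m\rangle},$$

and the predicted protein noise is

$$CV_p^2 = \frac{1}{\langle p\rangle}
  + \frac{1+b}{\langle m\rangle}\,\frac{\gamma_p}{\gamma_m + \gamma_p}.$$

Measured protein noise falling below this prediction (a positive "noise gap"
$CV^2_{\mathrm{Theory}} - CV^2_{\mathrm{Exp}}$) indicates active noise
suppression.

## Worked example

Generate a newborn-only snapshot population at the wild-type parameter point
($k_m = 0.21\ \mathrm{min}^{-1}$, $b = 0.95$, $\gamma_m = 0.615\
\mathrm{min}^{-1}$, $k_p = 0.15\ \mathrm{min}^{-1}$, $\gamma_p = 0.015\
\mathrm{min}^{-1}$) and infer the burst statistics back:

```python
from burstlab import (PopulationConfig, WT_PARAMS, make_population,
                      filter_newborns, nb_mle, burst_size, transcription_rate,
                      translation_rate, moment_summary, cv2_theory,
                      cv2_poisson_bound)

snap = make_population(PopulationConfig(params=WT_PARAMS, n_cells=2180,
                                        newborns_only=True, seed=7))
newborns = filter_newborns(snap)                  # area < 3.0 um^2
fit = nb_mle(newborns["mrna"].to_numpy())
mom = moment_summary(newborns)
print(f"NB fit: r = {fit.r:.3f}, p = {fit.p:.3f}")
print(f"burst size b = {burst_size(fit):.2f} molecules")
print(f"transcription rate k_m = {transcription_rate(fit, 0.615):.2f} min^-1")
print(f"translation rate k_p = "
      f"{translation_rate(0.015, mom.mean_p, mom.mean_m):.2f} min^-1")
print(f"CV2_theory = {cv2_theory(mom.mean_p, mom.mean_m, burst_size(fit), 0.615, 0.015):.3f}")
```

Output:

```
NB fit: r = 0.306, p = 0.480
burst size b = 1.09 molecules
transcription rate k_m = 0.19 min^-1
translation rate k_p = 0.14 min^-1
CV2_theory = 0.470
```

The fitted burst size (~1 molecule per burst) and transcription rate
(~0.2 bursts/min) recover the generating parameters within the sampling error
of a 2,180-cell experiment; the predicted protein CV² (~0.46) is what an
unregulated two-stage model implies at these low copy numbers, and is the
baseline against which measured protein noise is compared.

A command-line interface mirrors the library
(`burstlab simulate|calibrate|infer|compare`), e.g.:

```bash
burstlab simulate population wt.csv --condition wt --n-cells 2000 --newborns-only
burstlab infer burst wt.csv --gamma-m 0.615 --gamma-p 0.015
```

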