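# flowmax

Maximum-likelihood deconvolution of CFSE dye-dilution time courses, with
objective estimates of how well-determined — and how redundant — the fitted
cellular parameters are.

## The problem

CFSE binds covalently to cellular proteins, so each cell division halves a
cell's fluorescence: a flow-cytometry histogram of log fluorescence shows one
peak per generation. Deconvolving a time course of such histograms into
biologically intuitive quantities — what fraction of cells responds, how long
the first and later cell cycles take, how long cells survive, how many
divisions a lineage undergoes — is notoriously prone to over-interpretation:
staining variability, autofluorescence background and dye dilution blur the
peaks, and several combinations of cellular parameters can explain the same
data equally well.

`flowmax` addresses this with a three-step methodology:

1. **Cell fluorescence model.** Log fluorescence of generation *g* is a
   Gaussian with mean `log10((i0 + s − b)·r^g + b)` and generation-invariant
   width `sqrt(ln(1 + CV²))/ln 10`, where `i0` anchors the undivided peak,
   `r ≈ 0.5` is the per-division halving ratio, `b` the background and `CV`
   the staining coefficient of variation. Peak weights (cells per
   generation) are obtained analytically by non-negative least squares; the
   nonlinear parameters are fitted per time point, with each accepted fit
   constraining the next time point.
2. **fcyton population model.** Generational cell counts follow a
   renewal-equation model with *decoupled* fates: a fraction `F0` of the `N`
   founders responds and is protected from death until it divides; newborns
   of generation *g* split by progressor fractions `F_g` — derived from a
   truncated-Gaussian division destiny `(Dμ, Dσ)` — into cells that divide
   again and cells that die. Times to divide and die are lognormal, separate
   for undivided and divided cells (12 parameters). Fitting is *integrated*:
   simulated-annealing proposals are rendered as histograms through the
   fitted fluorescence model and scored directly against the data (objective
   MRSD+, a root-sum-of-squares with a Pearson-correlation factor). A
   classic competing-fates cyton variant is included for comparisons.
3. **Solution quality.** The fit is repeated from random starts; candidates
   within 0.1 normalized-percent-area-error (NPAE) points of the best are
   kept; per-parameter sensitivity ranges (NPAE +1 point) are computed;
   ranges are agglomeratively clustered into non-redundant
   maximum-likelihood solution ranges; clusters whose resampled median NPAE
   is more than 1 point above the best are discarded.

A synthetic-data generator reproduces the study conditions used to
characterise the method — random parameter draws from realistic ranges,
scheduled time points, analytic or event-sampled histogram rendering, and
per-peak count noise / per-time-point scale noise.

## Worked example

```python
import numpy as np
from flowmax import FcytonParams, simulate_fcyton, progressor_fractions

params = FcytonParams(N=1e4, F0=0.85, Dmu=3.5, Dsigma=1.0,
                      Ediv0=40, SDdiv0=10, Ediv1=10, SDdiv1=4,
                      Edie0=60, SDdie0=20, Edie1=80, SDdie1=30)
cm = simulate_fcyton(params, np.arange(0, 193, 24.0))
print(np.round(cm.total))
```

prints the total-population trajectory

```
[ 10000  10218  29532 102113 160612 154876 109285  58553  25800]
```

— the population is flat until first divisions complete (~40 h), expands
16-fold as responders burn through 3–4 divisions, then declines as divided
cells die. `examples/` contains narrative scripts for each capability:
population simulation, dye-model fitting (recovers `cv=0.18, r=0.5, b=100`
exactly from multi-peak histograms, with count errors below 0.01% of the
largest generation), end-to-end phenotyping, and chimeric-parameter
analysis. A thin CLI mirrors the pipeline stages
(`flowmax hist | fluor | fit | cluster | simulate | generate | chimera |
phenotype`).

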