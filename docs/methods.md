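# Methods

This note records the models, numerical choices and known limitations of
`flowmax` at the level a maintainer or reviewer needs to judge what the
package computes and what its tests demonstrate.

## Cell fluorescence model

Log10 CFSE fluorescence of a population that has divided `g` times is
modelled as a Gaussian with

- mean `mu_g = log10((i0 + s − b) · r^g + b)` — geometric dye dilution on
  the linear scale with an additive autofluorescence background `b`; `i0`
  is the manually anchored linear mean of the undivided population and `s`
  a small linear-scale shift correction fitted per time point;
- SD `sigma = sqrt(ln(1 + cv²)) / ln 10`, the lognormal identity mapping a
  generation-invariant linear-scale coefficient of variation to a constant
  log-scale width.

A histogram is the weighted sum of per-bin Gaussian masses, so the weights
(cells per generation) enter linearly and are fitted exactly by
non-negative least squares (`scipy.optimize.nnls`) at every proposal of the
nonlinear search. The four nonlinear parameters `(cv, r, b, s)` are fitted
per time point by bounded Nelder–Mead on the squared density deviation,
multi-started from the bound midpoint, the previous time point's fit, and a
seeded random point.

**Constraint propagation.** The accepted fit of time point *t* initialises
the search at *t+1* and narrows the `(cv, r, b)` bounds to ±10% around it —
but only for parameters that pass a local identifiability test: perturbing
the parameter by 5% of its global bound width must increase the fitted SSE
by more than a factor of 3 (plus a small absolute floor). The test is
essential: a first time point showing a single undivided peak pins `cv` but
carries no information about `r` or `b`; narrowing bounds around whatever
value the optimiser happened to stop at would poison every later time
point. `s` always keeps its global bounds (±10% of `i0`).

The number of modelled generations defaults to 8 peaks.

## fcyton population model

Twelve parameters: founder count `N`; responding fraction `F0`; division
destiny mean and SD `(Dμ, Dσ)` in generations; and mean/SD pairs (hours)
for four lognormal timing distributions — time to first division
`(E[Tdiv0], sd)`, later division times `(E[Tdiv1+], sd)`, death of
undivided cells `(E[Tdie0], sd)` and of divided cells `(E[Tdie1+], sd)`.
Lognormals are parameterised by their distribution mean and SD via moment
matching (`sigma² = ln(1 + SD²/E²)`, `mu = ln E − sigma²/2`); each SD is
restricted to at most its mean.

Fates are decoupled: of the founders, `N·F0` are committed to dividing
(division-event density `N·F0·φdiv0(t)`) and protected from death; the rest
die (`N·(1−F0)·ψdie0(t)`). Each division releases 2 daughters into the next
generation; a fraction `F_g` of generation-g newborns is committed to
dividing again (delay pdf `φdiv1`), the rest to dying (`ψdie1`). Progressor
fractions come from the destiny Gaussian's survivor function,
`S(g) = 1 − Φ((g − Dμ)/Dσ)`, as the ratio `F_g = S(g)/S(g−1)` clamped to
[0, 1] and evaluated literally from `S(0)` — the ratio form makes any
truncation constant cancel for `g ≥ 2`, and the `g = 1` convention is
isolated in `progressor_fractions` should a different one be preferred.
Terminal-generation cells committed to division have nowhere to go and
persist; the non-committed fraction dies via `ψdie1`.

Counts follow by integrating the fluxes: generation 0 loses its dividers and
diers; generation g gains `2·(gen g−1 dividers)` and loses its own. The
identity `total(t) + cumulative deaths = N + cumulative divisions` holds at
every grid point and is asserted over 200 random parameter draws in the
test suite.

The competing-fates cyton variant replaces the protected split by a race:
realised division flux `φ(t)·(1 − Ψdie(t))` and death flux
`ψ(t)·(1 − F·Φdiv(t))`, with the same bookkeeping. It exists for
comparisons with cyton-style fitting tools and reduces to the decoupled
model when deaths lie far beyond the observation window.

**Discretisation.** Dynamics are computed on a uniform grid (default
`dt = 0.5 h`) with trapezoid-rule causal convolutions and cumulative
trapezoid integration, then interpolated to the requested times. Refining
`dt` from 0.5 to 0.25 h moves counts by well under 0.5%. A sharp timing
pdf undersampled by the grid can integrate to slightly more than 1 under
the trapezoid rule and would overdraw cells, so grid pdfs with mass above
1 are renormalised (mass genuinely beyond the horizon stays truncated).
Small negative counts from quadrature roundoff are clamped at zero;
negatives beyond `1e-4·N` raise as an internal error.

## Objectives and fitting

Histogram objectives compare count-scaled densities per time point: MAD
(summed absolute deviations), MRSD (root of summed squares), and the
default MRSD+, which multiplies each time point's MRSD term by
`(2 − cor(H, M))`; the Pearson factor rewards shape agreement and is
dropped (no extra factor) when either histogram has zero variance. The
sequential baseline scores summed squared deviations of generational
counts. Fit quality is reported as NPAE — the cell-count-weighted mean over
time points (and runs) of half the absolute density difference, 0–100%.

The optimiser is simulated annealing: per-parameter Gaussian proposals with
width proportional to temperature and bound width, reflected at the bounds,
Metropolis acceptance, geometric cooling. The default schedule estimates
`T0` as the score SD over 50 random draws, cools by 0.95 with 100 proposals
per temperature and stops at `T0/1000`; batch experiments use a reduced
schedule (cooling 0.85, 20 proposals per temperature, ~900 proposals per
restart). Annealing locates the basin; a deterministic local polish then
sharpens the optimum — bounded trust-region least squares on the count (or
binwise histogram) residuals, which at zero temperature is the natural
continuation of greedy descent and is what lets weakly curved directions
(late death times, destiny mean) converge within a practical budget. The
`SD ≤ E` restriction is enforced during optimisation by projection.

Integrated fitting renders each proposal's counts through the fixed
per-time-point fluorescence model (`model histogram = bin-mass matrix ×
counts`), so bins are weighted naturally and no ad hoc count-comparison
function is needed. The end-to-end pipeline additionally seeds the
restart pool with one deterministic warm start: the sequential fit to the
NNLS-extracted counts, polished under the integrated objective — the
classic two-stage estimate competing on equal terms with the random
restarts.

## Solution quality

Candidates within 0.1 NPAE points of the best are kept. Each parameter of
each kept candidate is walked outward (others fixed) to the first value
where NPAE exceeds the candidate's score by 1 point — geometric probing
brackets the first crossing, bisection refines it to 1e-3 relative; a
parameter that never crosses before its global bound is reported at the
bound (insensitive). Clusters merge agglomeratively: among pairs whose
ranges overlap in *all* 12 parameters, the pair with the largest total
normalized overlap (sum over parameters of overlap/union length) merges;
merged ranges are intersections; the tracked average is the
distance-weighted combination pulled toward the cluster average farther
from the overlap midpoint and clamped inside the overlap. Ties break by
lowest member NPAE, then input order, making the procedure deterministic.
Finally each cluster is sampled uniformly and independently per parameter
(default 1000 draws) and clusters whose median NPAE exceeds the best
cluster's by more than 1 point are dropped — this removes ranges whose
interior combinations are unrealistic even though their corners fit.

## Synthetic data generator

The generator defines the study conditions for all recovery statistics.
Population parameters are drawn uniformly from: `N` 10³–10⁵, `F0` 0–1,
`Dμ` 1–10 generations, `Dσ` 0.1–3, all timing means 5–150 h, timing SDs
1–150 h re-drawn until `SD ≤ E`. Dye parameters: `cv` 0.1–0.35, `r`
0.45–0.55, `b` 50–500 a.u., `s` within ±10% of `i0`, `i0` 10⁵–10⁶ a.u.
Histograms use 256 uniform log10 bins spanning every generation mean ±4σ,
shared across the course, and are rendered analytically by default
(deterministic); an event-sampling mode draws individual cells for realism
tests. Schedules: ten points over 12–192 h (the standard panel), five- and
three-point subsets, four distributed points 24–144 h, four early points
12–48 h, and an eight-point schedule 12–168 h used for the data-quality
scenarios, whose reference phenotype is a wildtype-like LPS-stimulated
B-cell parameter set with dye settings `cv 0.18, r 0.5, b 100, s 0`. Noise
models: each generation's weight scaled by `1 + N(0, 0.1)` (count noise)
or each time point's total scaled likewise (scale noise), clamped at zero.

What the generator does **not** emulate: dye catabolism over time (handled
in practice by re-anchoring `i0` per time point), debris/doublet events,
spillover, multi-population mixtures beyond the count-noise proxy, and
instrument binning artefacts. Passing recovery tests therefore demonstrate
correctness of the deconvolution machinery under the model's own
assumptions, not robustness to every artefact of real cytometry data.

## Problem sizes

The recovery panels are run at 100 courses (fluorescence recovery) and 50
courses × 8 restarts (fits to perfect counts); the data-quality scenarios
use 60 restarts per course. These sizes give stable panel averages and
medians while keeping a full reproduction run in the tens of minutes on a
single core; all draws derive from a single seed.

## Known limitations

- One fluorescence channel; compensation is assumed done upstream.
- The Eq-level algebra of the dye and population models follows the
  package's reconstruction (documented above) — alternative conventions are
  isolated behind `generation_gaussian`, `progressor_fractions` and
  `simulate_fcyton`.
- Sensitivity ranges are one-dimensional; correlated parameter slabs are
  captured only through clustering and the final resampling filter.
- The annealing schedule is heuristic; pathological landscapes may need
  more restarts rather than deeper cooling.
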