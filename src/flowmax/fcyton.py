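"""Population dynamics of dividing and dying lymphocytes.

Two renewal-equation models of generational cell counts over time:

* ``simulate_fcyton`` — decoupled fates.  A fraction F0 of the N founder
  cells responds and is committed to dividing (protected from death until it
  does); the rest die.  In later generations the progressor fractions F_g,
  derived from a truncated-Gaussian "division destiny" with mean Dmu and SD
  Dsigma, split each newborn cohort into cells that will divide again and
  cells that will die.  Times to divide and die are lognormal, with separate
  distributions for undivided and divided cells (12 parameters in total).

* ``simulate_cyton`` — the classic competing-fates variant, in which every
  responding cell races independent division and death clocks; provided for
  comparison fitting against cyton-style tools.

Dynamics are integrated by trapezoidal convolution on a uniform time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from scipy.special import ndtr

__all__ = [
    "FcytonParams",
    "CountMatrix",
    "PARAM_NAMES",
    "DEFAULT_FCYTON_BOUNDS",
    "lognormal_from_moments",
    "progressor_fractions",
    "simulate_fcyton",
    "simulate_cyton",
]

#: Canonical parameter order used by the fitting engine.
PARAM_NAMES = (
    "N", "F0", "Dmu", "Dsigma",
    "Ediv0", "SDdiv0", "Ediv1", "SDdiv1",
    "Edie0", "SDdie0", "Edie1", "SDdie1",
)

#: Fitting / generation bounds (hours for timing parameters).  The SD of each
#: lognormal is additionally restricted to be <= its mean.
DEFAULT_FCYTON_BOUNDS: dict[str, tuple[float, float]] = {
    "N": (1e3, 1e5),
    "F0": (0.0, 1.0),
    "Dmu": (1.0, 10.0),
    "Dsigma": (0.1, 3.0),
    "Ediv0": (5.0, 150.0), "SDdiv0": (1.0, 150.0),
    "Ediv1": (5.0, 150.0), "SDdiv1": (1.0, 150.0),
    "Edie0": (5.0, 150.0), "SDdie0": (1.0, 150.0),
    "Edie1": (5.0, 150.0), "SDdie1": (1.0, 150.0),
}


@dataclass
class FcytonParams:
    """The 12 cellular parameters of the decoupled-fate population model."""

    N: float        # founder cell count
    F0: float       # fraction of undivided cells that respond
    Dmu: float      # division-destiny mean (generations)
    Dsigma: float   # division-destiny SD (generations)
    Ediv0: float    # mean time to first division (h)
    SDdiv0: float   # SD of time to first division (h)
    Ediv1: float    # mean time to later divisions (h)
    SDdiv1: float   # SD of time to later divisions (h)
    Edie0: float    # mean time to death, undivided cells (h)
    SDdie0: float   # SD of time to death, undivided cells (h)
    Edie1: float    # mean time to death, divided cells (h)
    SDdie1: float   # SD of time to death, divided cells (h)

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not 0 <= self.F0 <= 1:
            raise ValueError("F0 must lie in [0, 1]")
        for mean_name, sd_name in (("Ediv0", "SDdiv0"), ("Ediv1", "SDdiv1"),
                                   ("Edie0", "SDdie0"), ("Edie1", "SDdie1")):
            e, sd = getattr(self, mean_name), getattr(self, sd_name)
            if e <= 0 or sd <= 0:
                raise ValueError(f"{mean_name}/{sd_name} must be positive")
            if sd > e * (1 + 1e-9):
                raise ValueError(f"{sd_name} must not exceed {mean_name}")
        if self.Dsigma <= 0:
            raise ValueError("Dsigma must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "FcytonParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))

    def replace(self, **kw) -> "FcytonParams":
        return replace(self, **kw)


@dataclass
class CountMatrix:
    """Cells per generation (rows) at each requested time (columns)."""

    times: np.ndarray
    counts: np.ndarray  # shape (g_max, n_times)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[1] != self.times.size:
            raise ValueError("counts must have one column per time")

    @property
    def g_max(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def lognormal_from_moments(E: float, SD: float) -> stats.rv_continuous:
    """Lognormal distribution with the given distribution mean and SD.

    Moment matching: sigma^2 = ln(1 + SD^2/E^2), mu = ln(E) - sigma^2/2.
    """
    if E <= 0 or SD <= 0:
        raise ValueError("E and SD must be positive")
    sigma2 = math.log1p((SD / E) ** 2)
    sigma = math.sqrt(sigma2)
    mu = math.log(E) - sigma2 / 2.0
    return stats.lognorm(s=sigma, scale=math.exp(mu))


def _lognorm_pdf(t: np.ndarray, E: float, SD: float) -> np.ndarray:
    # inlined lognormal pdf (hot path: called for every objective evaluation)
    sigma2 = math.log1p((SD / E) ** 2)
    sigma = math.sqrt(sigma2)
    mu = math.log(E) - sigma2 / 2.0
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(-((np.log(tp) - mu) ** 2) / (2 * sigma2)) / (tp * sigma * math.sqrt(2 * math.pi))
    return out


def progressor_fractions(Dmu: float, Dsigma: float, g_max: int) -> np.ndarray:
    """F_g for g = 1..g_max-1: fraction of generation-g newborns that divide on.

    Ratio-of-survivors form of the division-destiny Gaussian:
    S(g) = 1 - Phi((g - Dmu)/Dsigma), F_g = S(g)/S(g-1), clamped to [0, 1].
    The returned array is indexed by generation with F[0] = nan (generation 0
    is governed by the independent responding fraction F0).
    """
    if Dsigma <= 0:
        raise ValueError("Dsigma must be positive")
    g = np.arange(g_max, dtype=float)
    S = 1.0 - ndtr((g - Dmu) / Dsigma)
    F = np.full(g_max, np.nan)
    for gg in range(1, g_max):
        F[gg] = 0.0 if S[gg - 1] <= 0 else min(1.0, S[gg] / S[gg - 1])
    return F


def _trapz_convolve(a: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoid-rule causal convolution of two sampled signals."""
    k = a.size
    full = np.convolve(a, b)[:k]
    # trapezoid correction: halve the two endpoint products of each sum
    full -= 0.5 * (a[0] * b + a * b[0])
    return full * dt


def _sampled_pdf(t: np.ndarray, E: float, SD: float, dt: float) -> np.ndarray:
    pdf = _lognorm_pdf(t, E, SD)
    # sharp pdfs undersampled by the grid can integrate to slightly more
    # than 1 under the trapezoid rule, which would overdraw cells; cap the
    # grid mass at 1 (mass genuinely beyond the horizon stays truncated)
    mass = np.trapezoid(pdf, dx=dt)
    if mass > 1.0:
        pdf = pdf / mass
    return pdf


def _grids(p: FcytonParams, times: np.ndarray, dt: float):
    t_end = float(np.max(times)) if times.size else 0.0
    k = max(2, int(math.ceil(t_end / dt)) + 1)
    t = np.arange(k) * dt
    pdiv0 = _sampled_pdf(t, p.Ediv0, p.SDdiv0, dt)
    pdiv1 = _sampled_pdf(t, p.Ediv1, p.SDdiv1, dt)
    pdie0 = _sampled_pdf(t, p.Edie0, p.SDdie0, dt)
    pdie1 = _sampled_pdf(t, p.Edie1, p.SDdie1, dt)
    return t, pdiv0, pdiv1, pdie0, pdie1


def _counts_from_fluxes(p, t, ndiv, ndie, times, g_max, dt) -> CountMatrix:
    counts_grid = np.empty((g_max, t.size))
    cum_div = cumulative_trapezoid(ndiv, dx=dt, initial=0.0, axis=1)
    cum_die = cumulative_trapezoid(ndie, dx=dt, initial=0.0, axis=1)
    counts_grid[0] = p.N - cum_div[0] - cum_die[0]
    for g in range(1, g_max):
        counts_grid[g] = 2.0 * cum_div[g - 1] - cum_div[g] - cum_die[g]
    if counts_grid.min() < -1e-4 * p.N:
        raise ArithmeticError(
            f"negative cell count {counts_grid.min():.3g} exceeds numerical tolerance"
        )
    counts_grid = np.maximum(counts_grid, 0.0)
    out = np.empty((g_max, times.size))
    for g in range(g_max):
        out[g] = np.interp(times, t, counts_grid[g])
    return CountMatrix(times=times, counts=out)


def simulate_fcyton(
    p: FcytonParams,
    times: Sequence[float],
    g_max: int = 8,
    dt: float = 0.5,
) -> CountMatrix:
    """Generational cell counts under decoupled division/death fates.

    Responding founders (fraction F0) divide after a lognormal delay and are
    protected from death; non-responders die.  Newborns of generation g split
    by F_g into further dividers and diers.  Cells in the terminal generation
    that are committed to division have nowhere to go and persist.
    """
    times = np.asarray(times, dtype=float)
    t, pdiv0, pdiv1, pdie0, pdie1 = _grids(p, times, dt)
    F = progressor_fractions(p.Dmu, p.Dsigma, g_max)
    ndiv = np.zeros((g_max, t.size))
    ndie = np.zeros((g_max, t.size))
    ndiv[0] = p.N * p.F0 * pdiv0
    ndie[0] = p.N * (1.0 - p.F0) * pdie0
    for g in range(1, g_max):
        born = 2.0 * ndiv[g - 1]
        if not born.any():
            break
        die_influx = _trapz_convolve(born, pdie1, dt)
        if g < g_max - 1:
            div_influx = _trapz_convolve(born, pdiv1, dt)
            ndiv[g] = F[g] * div_influx
            ndie[g] = (1.0 - F[g]) * die_influx
        else:
            # terminal generation: committed cells cannot divide further
            ndie[g] = (1.0 - F[g]) * die_influx
    return _counts_from_fluxes(p, t, ndiv, ndie, times, g_max, dt)


def simulate_cyton(
    p: FcytonParams,
    times: Sequence[float],
    g_max: int = 8,
    dt: float = 0.5,
) -> CountMatrix:
    """Generational counts under the classic competing-fates cyton dynamics.

    Every cell races an independent division clock (scaled by the progressor
    fraction) against a death clock; the realised division flux is
    phi(t)·(1 - Psi(t)) and the death flux psi(t)·(1 - F·Phi(t)).
    """
    times = np.asarray(times, dtype=float)
    t, pdiv0, pdiv1, pdie0, pdie1 = _grids(p, times, dt)
    F = progressor_fractions(p.Dmu, p.Dsigma, g_max)
    Phi_div0 = cumulative_trapezoid(pdiv0, dx=dt, initial=0.0)
    Phi_div1 = cumulative_trapezoid(pdiv1, dx=dt, initial=0.0)
    Psi_die0 = cumulative_trapezoid(pdie0, dx=dt, initial=0.0)
    Psi_die1 = cumulative_trapezoid(pdie1, dx=dt, initial=0.0)
    ndiv = np.zeros((g_max, t.size))
    ndie = np.zeros((g_max, t.size))
    ndiv[0] = p.N * p.F0 * pdiv0 * (1.0 - Psi_die0)
    ndie[0] = p.N * pdie0 * (1.0 - p.F0 * Phi_div0)
    eff_div1 = pdiv1 * (1.0 - Psi_die1)
    for g in range(1, g_max):
        born = 2.0 * ndiv[g - 1]
        if not born.any():
            break
        fg = F[g] if g < g_max - 1 else 0.0  # terminal generation cannot divide
        if fg > 0:
            ndiv[g] = fg * _trapz_convolve(born, eff_div1, dt)
        ndie[g] = _trapz_convolve(born, pdie1 * (1.0 - fg * Phi_div1), dt)
    return _counts_from_fluxes(p, t, ndiv, ndie, times, g_max, dt)
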