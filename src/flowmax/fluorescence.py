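"""Generation-indexed Gaussian mixture model of log CFSE fluorescence.

Each cell division halves the covalently bound dye, so a population that has
divided g times appears as a Gaussian peak in log10 fluorescence whose
linear-scale mean follows a background-additive geometric dilution::

    M_g = (i0 + s - b) * r**g + b

with ``i0`` the anchored mean fluorescence of the undivided population, ``s``
a small shift correction, ``b`` the autofluorescence background and ``r`` the
per-division halving ratio (~0.5).  Staining heterogeneity is captured by a
generation-invariant coefficient of variation ``cv``; on the log10 axis this
yields a common peak width via the lognormal identity
``sigma = sqrt(ln(1 + cv^2)) / ln(10)``.

Peak weights (cells per generation) are linear in the model and are fitted
analytically by non-negative least squares; the four nonlinear parameters
(cv, r, b, s) are fitted per time point by bounded local search, with each
accepted fit initialising and narrowing the bounds of the next time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize, nnls
from scipy.special import ndtr

from .io import Histogram, HistogramTimecourse

__all__ = [
    "FluorParams",
    "generation_gaussian",
    "gaussian_bin_matrix",
    "mixture_density",
    "fit_peak_weights",
    "fit_fluorescence_timecourse",
    "DEFAULT_FLUOR_BOUNDS",
]

#: Default fitting bounds for the nonlinear fluorescence parameters.
#: s bounds are expressed as a fraction of i0 and resolved per time point.
DEFAULT_FLUOR_BOUNDS: dict[str, tuple[float, float]] = {
    "cv": (0.05, 0.5),
    "r": (0.4, 0.6),
    "b": (10.0, 1000.0),
    "s_frac": (-0.1, 0.1),
}


@dataclass
class FluorParams:
    """Per-time-point dye model parameters (linear a.u. unless noted)."""

    cv: float       # generation-invariant coefficient of variation
    r: float        # dye halving ratio per division, ~0.5
    b: float        # background autofluorescence
    s: float        # shift correction to the undivided-population fluorescence
    i0: float       # anchored linear mean fluorescence of undivided cells
    g_max: int = 8  # number of modelled generations (peaks)

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if not 0 < self.r < 1:
            raise ValueError("r must lie in (0, 1)")
        if self.b < 0:
            raise ValueError("b must be non-negative")
        if self.i0 + self.s <= self.b:
            raise ValueError("i0 + s must exceed b so every peak mean is positive")
        if self.g_max < 1:
            raise ValueError("g_max must be >= 1")

    @property
    def sigma_log10(self) -> float:
        return math.sqrt(math.log1p(self.cv ** 2)) / math.log(10.0)


def generation_gaussian(p: FluorParams, g: int) -> tuple[float, float]:
    """Mean and SD (log10 units) of the generation-``g`` peak."""
    if not 0 <= g < p.g_max:
        raise ValueError(f"generation {g} outside [0, {p.g_max})")
    linear_mean = (p.i0 + p.s - p.b) * p.r ** g + p.b
    if linear_mean <= 0:
        raise ValueError("non-positive linear peak mean")
    return math.log10(linear_mean), p.sigma_log10


def gaussian_bin_matrix(p: FluorParams, bin_edges: np.ndarray) -> np.ndarray:
    """Per-bin Gaussian mass for every generation: shape (n_bins, g_max).

    Column g integrates the generation-g Gaussian over each bin, so
    ``A @ w`` is the model histogram for peak weights ``w``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    g = np.arange(p.g_max)
    mu = np.log10((p.i0 + p.s - p.b) * p.r ** g + p.b)
    sigma = p.sigma_log10
    z = (edges[:, None] - mu[None, :]) / sigma
    cdf = ndtr(z)
    return cdf[1:, :] - cdf[:-1, :]


def mixture_density(p: FluorParams, w: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Model histogram counts: weighted Gaussian mass per bin."""
    w = np.asarray(w, dtype=float)
    if w.size != p.g_max:
        raise ValueError("one weight per generation required")
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and non-negative")
    return gaussian_bin_matrix(p, bin_edges) @ w


def fit_peak_weights(p: FluorParams, h: Histogram) -> np.ndarray:
    """Cells per generation by non-negative least squares against ``h``.

    The mixture is linear in the weights, so this is the exact analytic
    minimiser of the squared per-bin deviation subject to w >= 0.
    """
    if h.counts.sum() == 0:
        return np.zeros(p.g_max)
    A = gaussian_bin_matrix(p, h.bin_edges)
    w, _ = nnls(A, h.counts)
    return w


# ---------------------------------------------------------------------------
# Per-time-point nonlinear fitting
# ---------------------------------------------------------------------------

def _resolve_bounds(bounds: dict[str, tuple[float, float]], i0: float) -> list[tuple[float, float]]:
    s_lo, s_hi = bounds.get("s_frac", DEFAULT_FLUOR_BOUNDS["s_frac"])
    return [
        tuple(bounds.get("cv", DEFAULT_FLUOR_BOUNDS["cv"])),
        tuple(bounds.get("r", DEFAULT_FLUOR_BOUNDS["r"])),
        tuple(bounds.get("b", DEFAULT_FLUOR_BOUNDS["b"])),
        (s_lo * i0, s_hi * i0),
    ]


def _make_params(theta: np.ndarray, i0: float, g_max: int) -> Optional[FluorParams]:
    cv, r, b, s = theta
    if i0 + s <= b:
        return None
    try:
        return FluorParams(cv=cv, r=r, b=b, s=s, i0=i0, g_max=g_max)
    except ValueError:
        return None


def _density_sse(theta: np.ndarray, h: Histogram, dens: np.ndarray,
                 i0: float, g_max: int) -> float:
    p = _make_params(theta, i0, g_max)
    if p is None:
        return 1e6
    A = gaussian_bin_matrix(p, h.bin_edges)
    w, _ = nnls(A, h.counts)
    model = A @ w
    tot = model.sum()
    if tot <= 0:
        return 1e6
    resid = model / h.counts.sum() - dens
    return float(resid @ resid)


def _fit_single_histogram(
    h: Histogram,
    i0: float,
    bounds: list[tuple[float, float]],
    g_max: int,
    rng: np.random.Generator,
    x0_extra: Optional[np.ndarray],
    n_random_starts: int = 1,
) -> tuple[np.ndarray, float, bool]:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    dens = h.density()
    starts = [0.5 * (lo + hi)]
    if x0_extra is not None:
        starts.append(np.clip(x0_extra, lo, hi))
    for _ in range(n_random_starts):
        starts.append(lo + rng.random(4) * (hi - lo))

    def wrapped(theta: np.ndarray) -> float:
        return _density_sse(np.clip(theta, lo, hi), h, dens, i0, g_max)

    best_x, best_f, converged = starts[0], np.inf, False
    for x0 in starts:
        res = minimize(wrapped, x0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-12,
                                "maxiter": 800, "adaptive": True})
        if res.fun < best_f:
            best_x, best_f, converged = np.clip(res.x, lo, hi), float(res.fun), bool(res.success)
    return best_x, best_f, converged


def fit_fluorescence_timecourse(
    tc: HistogramTimecourse,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
    g_max: int = 8,
    narrow: float = 0.1,
) -> list[tuple[FluorParams, np.ndarray]]:
    """Fit (cv, r, b, s) per time point; weights by NNLS at every proposal.

    The accepted fit of time point t initialises the search at t+1 and
    narrows the (cv, r, b) bounds to ±``narrow`` (multiplicative) around it —
    but only for parameters the histogram actually constrains.  A single
    undivided peak pins cv yet says nothing about the halving ratio or the
    background, so each parameter must pass a perturbation test (moving it
    by 5% of its bound width must worsen the fit appreciably) before its
    bounds are carried forward.  Unidentified parameters keep their global
    bounds until a later histogram resolves them.
    """
    base_bounds = dict(DEFAULT_FLUOR_BOUNDS)
    if bounds:
        base_bounds.update(bounds)
    rng = np.random.default_rng(seed)
    results: list[tuple[FluorParams, np.ndarray]] = []
    prev_x: Optional[np.ndarray] = None
    prev_identified = np.zeros(3, dtype=bool)
    for h, i0 in zip(tc.histograms, tc.undivided_mean):
        blist = _resolve_bounds(base_bounds, i0)
        if prev_x is not None:
            for k in range(3):  # cv, r, b candidates; s keeps its global bounds
                if not prev_identified[k]:
                    continue
                centre = prev_x[k]
                lo = max(blist[k][0], centre * (1 - narrow))
                hi = min(blist[k][1], centre * (1 + narrow))
                if lo < hi:
                    blist[k] = (lo, hi)
        x, fval, _ = _fit_single_histogram(h, i0, blist, g_max, rng, prev_x)
        glob = _resolve_bounds(base_bounds, i0)
        dens = h.density()
        for k in range(3):
            width = glob[k][1] - glob[k][0]
            worst = 0.0
            for sign in (-1.0, 1.0):
                y = x.copy()
                y[k] = min(max(y[k] + sign * 0.05 * width, glob[k][0]), glob[k][1])
                worst = max(worst, _density_sse(y, h, dens, i0, g_max))
            prev_identified[k] = worst > 3.0 * fval + 1e-9
        p = _make_params(x, i0, g_max)
        if p is None:  # degenerate corner: fall back to mid-bounds
            mid = np.array([0.5 * (b[0] + b[1]) for b in blist])
            mid[3] = 0.0
            p = _make_params(mid, i0, g_max)
            assert p is not None
        w = fit_peak_weights(p, h)
        results.append((p, w))
        prev_x = x
    return results
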