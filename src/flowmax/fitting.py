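"""Objective functions and the stochastic fitting engine.

The population model is fitted either *sequentially* (scored against
generational cell counts extracted beforehand) or *integrated* (scored
against the fluorescence histograms themselves, with the fitted per-time
fluorescence model acting as an adaptor that renders any proposed count
vector as a model histogram).

Fit quality is summarised by the normalized percent area error (NPAE): the
cell-count-weighted mean, over time points and runs, of half the absolute
difference between model and data histogram densities — 0% for identical
histograms, 100% for disjoint ones.

The optimiser is simulated annealing (Metropolis acceptance, per-parameter
Gaussian proposals scaled with temperature, reflection at the bounds),
followed by a deterministic local polish of the best point found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .fcyton import (DEFAULT_FCYTON_BOUNDS, PARAM_NAMES, CountMatrix,
                     FcytonParams, simulate_cyton, simulate_fcyton)
from .fluorescence import FluorParams, gaussian_bin_matrix
from .io import HistogramTimecourse

__all__ = [
    "AnnealSchedule",
    "SolutionCandidate",
    "npae",
    "objective",
    "anneal",
    "integrated_fit",
    "sequential_fit",
    "bounds_arrays",
]

OBJECTIVE_KINDS = ("SD_counts", "MAD", "MRSD", "MRSD_plus", "NPAE")


@dataclass
class AnnealSchedule:
    """Simulated-annealing control parameters.

    T0 is estimated from the score SD over ``n_t0_draws`` random draws when
    not given.  Cooling is geometric; the run stops once T < T0 * stop_frac.
    """

    T0: Optional[float] = None
    cooling: float = 0.95
    steps_per_temp: int = 100
    stop_frac: float = 1e-3
    step_scale: float = 0.4
    min_step_frac: float = 0.01
    n_t0_draws: int = 50


#: Reduced schedule used by the batch recovery experiments; same engine,
#: roughly 900 proposals per restart before the deterministic polish.
FAST_SCHEDULE = AnnealSchedule(cooling=0.85, steps_per_temp=20, n_t0_draws=20)


@dataclass
class SolutionCandidate:
    """One fitted parameter set with its score and provenance."""

    params: FcytonParams
    score: float
    npae: Optional[float] = None
    seed: int = 0
    converged: bool = True
    fluor: Optional[list[FluorParams]] = None
    sensitivity: Optional[dict[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.npae is not None and not (0.0 <= self.npae <= 100.0 + 1e-9):
            raise ValueError("npae must lie in [0, 100]")


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _as_density(h: np.ndarray) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    tot = h.sum()
    return h / tot if tot > 0 else np.zeros_like(h)


def npae(
    model_hists: Sequence[np.ndarray],
    data_hists: Sequence[np.ndarray],
    totals: Optional[Sequence[float]] = None,
    weighted: bool = True,
) -> float:
    """Normalized percent area error between model and data histograms.

    Per time point the histograms are normalised to densities and half their
    absolute difference is taken (the total-variation distance, in [0, 1]);
    the result is the cell-count-weighted mean across time points and runs,
    expressed in percent.
    """
    if len(model_hists) != len(data_hists):
        raise ValueError("model and data time points differ")
    if totals is None:
        totals = [float(np.sum(h)) for h in data_hists]
    areas = np.empty(len(data_hists))
    w = np.asarray(totals, dtype=float)
    for i, (m, h) in enumerate(zip(model_hists, data_hists)):
        m = np.asarray(m, dtype=float)
        h = np.asarray(h, dtype=float)
        if m.shape != h.shape:
            raise ValueError("histogram grids differ between model and data")
        areas[i] = 0.5 * np.abs(_as_density(h) - _as_density(m)).sum()
    if not weighted:
        return 100.0 * float(areas.mean())
    if w.sum() <= 0:
        return 0.0
    return 100.0 * float((w * areas).sum() / w.sum())


def objective(
    kind: str,
    model_hists: Sequence[np.ndarray],
    data_hists: Sequence[np.ndarray],
    totals: Optional[Sequence[float]] = None,
) -> float:
    """Histogram-comparison objective; lower is better, 0 iff model == data.

    MAD sums absolute deviations of count-scaled densities; MRSD takes the
    root of the summed squared deviations; MRSD+ multiplies each time point's
    MRSD term by (2 - Pearson correlation), rewarding shape agreement.
    SD_counts (for the sequential route) is handled by ``sd_counts``.
    """
    if kind not in OBJECTIVE_KINDS:
        raise ValueError(f"unknown objective {kind!r}; choose from {OBJECTIVE_KINDS}")
    if kind == "NPAE":
        return npae(model_hists, data_hists, totals)
    if kind == "SD_counts":
        raise ValueError("SD_counts compares counts, not histograms; use sd_counts()")
    if totals is None:
        totals = [float(np.sum(h)) for h in data_hists]
    terms = []
    for m, h, cells in zip(model_hists, data_hists, totals):
        hd = _as_density(h) * cells
        md = _as_density(m) * cells
        diff = hd - md
        if kind == "MAD":
            terms.append(np.abs(diff).sum())
            continue
        term = math.sqrt(float(diff @ diff))
        if kind == "MRSD_plus":
            sh, sm = np.std(hd), np.std(md)
            if sh > 0 and sm > 0:
                cor = float(np.corrcoef(hd, md)[0, 1])
                term *= (2.0 - cor)
            # zero-variance histogram: correlation undefined, no extra factor
        terms.append(term)
    return float(np.mean(terms))


def sd_counts(model: np.ndarray, data: np.ndarray) -> float:
    """Summed squared deviation between generational count matrices."""
    d = np.asarray(model, dtype=float) - np.asarray(data, dtype=float)
    return float((d * d).sum())


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

def bounds_arrays(bounds: Optional[dict[str, tuple[float, float]]] = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    merged = dict(DEFAULT_FCYTON_BOUNDS)
    if bounds:
        merged.update(bounds)
    lo = np.array([merged[n][0] for n in PARAM_NAMES])
    hi = np.array([merged[n][1] for n in PARAM_NAMES])
    return lo, hi


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def anneal(
    score_fn: Callable[[np.ndarray], float],
    lo: np.ndarray,
    hi: np.ndarray,
    seed: int = 0,
    schedule: Optional[AnnealSchedule] = None,
    x0: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimise ``score_fn`` over the box [lo, hi] by simulated annealing.

    Proposals are per-parameter Gaussian steps whose width shrinks with
    temperature and is reflected at the bounds; Metropolis acceptance on the
    score.  Deterministic for a fixed seed.  Returns the best-ever point, its
    score and the per-temperature trace of best scores.
    """
    sch = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    width = hi - lo
    x = np.asarray(x0, dtype=float) if x0 is not None else lo + rng.random(lo.size) * width
    x = np.clip(x, lo, hi)
    f = score_fn(x)
    T0 = sch.T0
    if T0 is None:
        draws = [score_fn(lo + rng.random(lo.size) * width) for _ in range(sch.n_t0_draws)]
        T0 = float(np.std(draws))
        if T0 <= 0 or not np.isfinite(T0):
            T0 = max(abs(f), 1.0)
    best_x, best_f = x.copy(), f
    trace: list[float] = []
    T = T0
    while T > T0 * sch.stop_frac:
        frac = max(T / T0, sch.min_step_frac)
        step = sch.step_scale * width * frac
        for _ in range(sch.steps_per_temp):
            prop = _reflect(x + rng.normal(size=lo.size) * step, lo, hi)
            fp = score_fn(prop)
            if fp <= f or rng.random() < math.exp(-(fp - f) / T):
                x, f = prop, fp
                if f < best_f:
                    best_x, best_f = x.copy(), f
        trace.append(best_f)
        T *= sch.cooling
    return best_x, best_f, trace


# ---------------------------------------------------------------------------
# Parameter-vector plumbing
# ---------------------------------------------------------------------------

_SD_IDX = [PARAM_NAMES.index(n) for n in ("SDdiv0", "SDdiv1", "SDdie0", "SDdie1")]
_E_IDX = [PARAM_NAMES.index(n) for n in ("Ediv0", "Ediv1", "Edie0", "Edie1")]


def project_sd_le_e(x: np.ndarray) -> np.ndarray:
    """Project the SD <= E restriction of the timing distributions."""
    y = np.array(x, dtype=float)
    for si, ei in zip(_SD_IDX, _E_IDX):
        y[si] = min(y[si], y[ei])
    return y


def params_from_vector(x: np.ndarray) -> FcytonParams:
    return FcytonParams.from_array(project_sd_le_e(x))


# ---------------------------------------------------------------------------
# High-level fits
# ---------------------------------------------------------------------------

def render_model_histograms(
    counts: CountMatrix,
    fluor: Sequence[FluorParams],
    bin_edges: np.ndarray,
) -> list[np.ndarray]:
    """Adaptor: render generational counts as model histograms per time point."""
    return [gaussian_bin_matrix(fp, bin_edges) @ counts.counts[:, i]
            for i, fp in enumerate(fluor)]


def _polish_histogram_objective(score_fn, x, lo, hi, maxiter=400):
    res = minimize(lambda z: score_fn(np.clip(z, lo, hi)), x, method="Nelder-Mead",
                   options={"maxiter": maxiter, "adaptive": True,
                            "xatol": 1e-6, "fatol": 1e-10})
    return np.clip(res.x, lo, hi), float(res.fun)


def integrated_fit(
    tc: HistogramTimecourse,
    fluor: Sequence[FluorParams],
    n_restarts: int = 100,
    objective_kind: str = "MRSD_plus",
    seed: int = 0,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    schedule: Optional[AnnealSchedule] = None,
    g_max: int = 8,
    dt: float = 0.5,
    polish: bool = True,
    model: str = "fcyton",
    warm_starts: Optional[Sequence[np.ndarray]] = None,
) -> list[SolutionCandidate]:
    """Fit the population model directly to fluorescence histograms.

    Each annealing proposal is simulated, rendered through the fixed
    fluorescence model, and scored with ``objective_kind`` against the data
    densities.  One candidate per restart, sorted by final NPAE.

    ``warm_starts`` adds deterministic candidates polished directly from the
    given parameter vectors (e.g. a sequential fit to extracted counts) —
    the classic two-stage estimate joining the random-restart pool.
    """
    lo, hi = bounds_arrays(bounds)
    data = [h.counts for h in tc.histograms]
    totals = [h.total_cells for h in tc.histograms]
    times = tc.times
    edges = tc.bin_edges
    simulate = simulate_fcyton if model == "fcyton" else simulate_cyton
    A_mats = [gaussian_bin_matrix(fp, edges) for fp in fluor]

    def score(x: np.ndarray) -> float:
        try:
            cm = simulate(params_from_vector(x), times, g_max=g_max, dt=dt)
        except (ValueError, ArithmeticError):
            return 1e9
        model_h = [A_mats[i] @ cm.counts[:, i] for i in range(len(fluor))]
        return objective(objective_kind, model_h, data, totals)

    def score_npae(x: np.ndarray) -> float:
        cm = simulate(params_from_vector(x), times, g_max=g_max, dt=dt)
        model_h = [A_mats[i] @ cm.counts[:, i] for i in range(len(fluor))]
        return npae(model_h, data, totals)

    data_scaled = [totals[i] * (d / d.sum() if d.sum() > 0 else d)
                   for i, d in enumerate(data)]

    def residuals(x: np.ndarray) -> np.ndarray:
        # binwise count-scaled density residuals: the squared-deviation core
        # shared by all histogram objectives, used for the local polish
        try:
            cm = simulate(params_from_vector(x), times, g_max=g_max, dt=dt)
        except (ValueError, ArithmeticError):
            return np.full(sum(d.size for d in data), 1e6)
        res = []
        for i in range(len(fluor)):
            m = A_mats[i] @ cm.counts[:, i]
            tot = m.sum()
            md = totals[i] * (m / tot) if tot > 0 else m
            res.append(md - data_scaled[i])
        return np.concatenate(res)

    eps = 1e-9 * (hi - lo)

    def polish_ls(x: np.ndarray) -> np.ndarray:
        res = least_squares(residuals, np.clip(x, lo + eps, hi - eps),
                            bounds=(lo, hi), x_scale=np.maximum(hi - lo, 1e-12),
                            diff_step=1e-4, max_nfev=150)
        return res.x

    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    out: list[SolutionCandidate] = []
    for k, ws in enumerate(warm_starts or []):
        x = polish_ls(np.asarray(ws, dtype=float))
        out.append(SolutionCandidate(
            params=params_from_vector(x), score=score(x),
            npae=min(100.0, score_npae(x)), seed=-(k + 1), fluor=list(fluor)))
    for rs in restart_seeds:
        x, fval, _ = anneal(score, lo, hi, seed=int(rs), schedule=schedule)
        if polish:
            x_p = polish_ls(x)
            if score(x_p) <= fval:
                x = x_p
            fval = score(x)
        out.append(SolutionCandidate(
            params=params_from_vector(x), score=fval,
            npae=min(100.0, score_npae(x)), seed=int(rs),
            fluor=list(fluor)))
    out.sort(key=lambda c: c.npae)
    return out


def sequential_fit(
    counts: CountMatrix,
    n_restarts: int = 8,
    seed: int = 0,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    schedule: Optional[AnnealSchedule] = None,
    g_max: Optional[int] = None,
    dt: float = 0.5,
    polish: bool = True,
    model: str = "fcyton",
) -> SolutionCandidate:
    """Fit the population model to extracted generational counts (SD score).

    The classic two-stage baseline: anneal against the squared count
    deviation, keep the best restart, and polish it with a bounded
    least-squares pass on the count residuals.
    """
    g_max = g_max or counts.g_max
    lo, hi = bounds_arrays(bounds)
    times = counts.times
    data = counts.counts
    simulate = simulate_fcyton if model == "fcyton" else simulate_cyton
    if times.size < 2:
        # a single time point cannot constrain 12 parameters
        mid = params_from_vector(0.5 * (lo + hi))
        return SolutionCandidate(params=mid, score=math.inf, seed=seed, converged=False)

    def score(x: np.ndarray) -> float:
        try:
            cm = simulate(params_from_vector(x), times, g_max=g_max, dt=dt)
        except (ValueError, ArithmeticError):
            return 1e18
        return sd_counts(cm.counts, data)

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            cm = simulate(params_from_vector(x), times, g_max=g_max, dt=dt)
        except (ValueError, ArithmeticError):
            return np.full(data.size, 1e9)
        return (cm.counts - data).ravel()

    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best_x, best_f = None, math.inf
    for rs in restart_seeds:
        x, fval, _ = anneal(score, lo, hi, seed=int(rs), schedule=schedule)
        if polish:
            eps = 1e-9 * (hi - lo)
            res = least_squares(residuals, np.clip(x, lo + eps, hi - eps),
                                bounds=(lo, hi), x_scale=np.maximum(hi - lo, 1e-12),
                                diff_step=1e-4, max_nfev=200)
            x, fval = res.x, float(2 * res.cost)  # cost = 0.5 * sum(resid^2)
        if fval < best_f:
            best_x, best_f = x, fval
    return SolutionCandidate(params=params_from_vector(best_x), score=best_f, seed=seed)
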