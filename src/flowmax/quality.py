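"""Solution sensitivity, redundancy, and maximum-likelihood ranges.

Repeated stochastic fitting yields many candidate parameter sets.  This
module turns them into a small number of *non-redundant maximum-likelihood
solution ranges*:

1. keep candidates whose NPAE is within 0.1 percentage points of the best;
2. for each candidate, walk each parameter outward (all others fixed) to the
   values where NPAE rises by a tolerance (1 point) — its sensitivity range;
3. agglomeratively merge candidates whose ranges overlap in *every*
   parameter, always merging the pair with the highest total normalized
   overlap; merged ranges are intersections, and a distance-weighted average
   is tracked inside the overlap;
4. finally, sample each surviving cluster uniformly within its ranges and
   drop clusters whose median NPAE is more than 1 point above the best —
   removing ranges that harbour unrealistic parameter combinations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .fcyton import PARAM_NAMES, FcytonParams
from .fitting import SolutionCandidate, bounds_arrays, params_from_vector

__all__ = [
    "SolutionCluster",
    "filter_candidates",
    "sensitivity",
    "cluster_solutions",
    "final_filter",
    "sample_cluster",
]

log = logging.getLogger(__name__)

NpaeFn = Callable[[np.ndarray], float]


@dataclass(eq=False)
class SolutionCluster:
    """A non-redundant solution: member fits plus their common ranges."""

    members: list[SolutionCandidate]
    ranges: dict[str, tuple[float, float]]
    average: np.ndarray
    median_npae: Optional[float] = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo > hi + 1e-12:
                raise ValueError(f"empty range for {name}")

    @property
    def best_npae(self) -> float:
        vals = [m.npae for m in self.members if m.npae is not None]
        return min(vals) if vals else math.inf

    def average_params(self) -> FcytonParams:
        return params_from_vector(self.average)


def filter_candidates(
    cands: Sequence[SolutionCandidate], window: float = 0.1
) -> list[SolutionCandidate]:
    """Keep candidates with NPAE within ``window`` points of the best."""
    if not cands:
        raise ValueError("no candidates to filter")
    best = min(c.npae for c in cands)
    return [c for c in cands if c.npae <= best + window]


# ---------------------------------------------------------------------------
# One-dimensional sensitivity ranges
# ---------------------------------------------------------------------------

def _first_crossing(
    f: Callable[[float], float],
    start: float,
    bound: float,
    target: float,
    rtol: float,
    n_probe: int = 12,
) -> float:
    """Leftmost value in [start, bound] (directed) where f crosses target.

    Probes geometrically outward to bracket the first crossing (robust to
    non-monotone NPAE profiles), then bisects the bracket.
    """
    if start == bound:
        return bound
    span = bound - start
    prev = start
    bracket = None
    for k in range(1, n_probe + 1):
        x = start + span * (2.0 ** (k - n_probe))
        if k == n_probe:
            x = bound
        if f(x) >= target:
            bracket = (prev, x)
            break
        prev = x
    if bracket is None:
        return bound  # never crosses: parameter insensitive to the bound
    a, b = bracket
    while abs(b - a) > rtol * max(abs(span), 1e-12):
        m = 0.5 * (a + b)
        if f(m) >= target:
            b = m
        else:
            a = m
    return 0.5 * (a + b)


def sensitivity(
    cand: SolutionCandidate,
    npae_fn: NpaeFn,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    tol: float = 1.0,
    rtol: float = 1e-3,
) -> dict[str, tuple[float, float]]:
    """Per-parameter interval over which NPAE stays within ``tol`` points.

    Each of the 12 parameters is varied independently, the others held at
    the candidate's values; an endpoint that reaches the global bound
    without the NPAE crossing base + tol is reported at the bound.
    """
    lo, hi = bounds_arrays(bounds)
    x = cand.params.to_array()
    base = npae_fn(x) if cand.npae is None else cand.npae
    target = base + tol
    ranges: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(PARAM_NAMES):
        if tol == 0:
            ranges[name] = (x[i], x[i])
            continue

        def f(v: float, i=i) -> float:
            y = x.copy()
            y[i] = v
            return npae_fn(y)

        lo_i = _first_crossing(f, x[i], lo[i], target, rtol)
        hi_i = _first_crossing(f, x[i], hi[i], target, rtol)
        ranges[name] = (min(lo_i, x[i]), max(hi_i, x[i]))
    cand.sensitivity = ranges
    return ranges


# ---------------------------------------------------------------------------
# Agglomerative clustering of sensitivity ranges
# ---------------------------------------------------------------------------

def _overlap(a: tuple[float, float], b: tuple[float, float]) -> Optional[tuple[float, float]]:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return (lo, hi) if lo <= hi else None


def _total_normalized_overlap(ra: dict, rb: dict) -> Optional[float]:
    """Sum over parameters of overlap/union length; None if any parameter
    fails to overlap."""
    total = 0.0
    for name in PARAM_NAMES:
        ov = _overlap(ra[name], rb[name])
        if ov is None:
            return None
        union = max(ra[name][1], rb[name][1]) - min(ra[name][0], rb[name][0])
        total += 1.0 if union <= 0 else (ov[1] - ov[0]) / union
    return total


def _merge_average(avg_a: np.ndarray, avg_b: np.ndarray,
                   ranges: dict[str, tuple[float, float]]) -> np.ndarray:
    """Distance-weighted average kept inside the merged overlap.

    Per parameter the new average sits between the two cluster averages,
    weighted toward the one lying farther from the overlap midpoint, then
    clamped into the overlap.
    """
    out = np.empty(len(PARAM_NAMES))
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = ranges[name]
        mid = 0.5 * (lo + hi)
        da, db = abs(avg_a[i] - mid), abs(avg_b[i] - mid)
        if da + db > 0:
            v = (da * avg_a[i] + db * avg_b[i]) / (da + db)
        else:
            v = 0.5 * (avg_a[i] + avg_b[i])
        out[i] = min(max(v, lo), hi)
    return out


def cluster_solutions(cands: Sequence[SolutionCandidate]) -> list[SolutionCluster]:
    """Agglomerate candidates into non-redundant solution clusters.

    Repeatedly merges the pair of clusters with the highest total normalized
    overlap among pairs overlapping in all parameters; stops when none
    remains.  Deterministic: ties break by lowest member NPAE, then by input
    index.
    """
    clusters: list[SolutionCluster] = []
    for c in cands:
        if c.sensitivity is None:
            raise ValueError("candidates must carry sensitivity ranges; run sensitivity() first")
        clusters.append(SolutionCluster(
            members=[c], ranges=dict(c.sensitivity), average=c.params.to_array()))
    order = {id(cl): i for i, cl in enumerate(clusters)}
    while len(clusters) > 1:
        best = None  # (overlap, -?, i, j)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ov = _total_normalized_overlap(clusters[i].ranges, clusters[j].ranges)
                if ov is None:
                    continue
                key = (-ov,
                       min(clusters[i].best_npae, clusters[j].best_npae),
                       min(order[id(clusters[i])], order[id(clusters[j])]),
                       i, j)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        i, j = best[3], best[4]
        a, b = clusters[i], clusters[j]
        merged_ranges = {name: _overlap(a.ranges[name], b.ranges[name])
                         for name in PARAM_NAMES}
        merged = SolutionCluster(
            members=a.members + b.members,
            ranges=merged_ranges,
            average=_merge_average(a.average, b.average, merged_ranges),
        )
        order[id(merged)] = min(order[id(a)], order[id(b)])
        clusters = [cl for k, cl in enumerate(clusters) if k not in (i, j)] + [merged]
    clusters.sort(key=lambda cl: (cl.best_npae, order[id(cl)]))
    return clusters


# ---------------------------------------------------------------------------
# Final resampling filter and sampling
# ---------------------------------------------------------------------------

def sample_cluster(cluster: SolutionCluster, n: int, seed: int = 0) -> np.ndarray:
    """Uniform independent per-parameter draws within the cluster ranges."""
    rng = np.random.default_rng(seed)
    lo = np.array([cluster.ranges[name][0] for name in PARAM_NAMES])
    hi = np.array([cluster.ranges[name][1] for name in PARAM_NAMES])
    return lo + rng.random((n, len(PARAM_NAMES))) * (hi - lo)


def final_filter(
    clusters: Sequence[SolutionCluster],
    npae_fn: NpaeFn,
    n_samples: int = 1000,
    seed: int = 0,
    window: float = 1.0,
) -> list[SolutionCluster]:
    """Keep clusters whose resampled median NPAE is within ``window`` of the best.

    Sampling is uniform and independent per parameter, so a cluster whose
    ranges admit unrealistic parameter combinations scores poorly and is
    dropped even if its member fits were good.
    """
    if not clusters:
        raise ValueError("no clusters to filter")
    rng = np.random.default_rng(seed)
    for cl in clusters:
        draws = sample_cluster(cl, n_samples, seed=int(rng.integers(0, 2**31 - 1)))
        scores = [npae_fn(draw) for draw in draws]
        cl.median_npae = float(np.median(scores))
    best = min(cl.median_npae for cl in clusters)
    kept = [cl for cl in clusters if cl.median_npae <= best + window]
    if len(kept) < len(clusters):
        log.info("final filter dropped %d of %d clusters", len(clusters) - len(kept), len(clusters))
    return kept
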