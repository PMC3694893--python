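"""Batch recovery experiments on generated panels.

These reproduce the two standard accuracy characterisations:

* ``fluorescence_recovery_panel`` — render noise-free courses from random
  parameter draws, fit the dye model per histogram, and score the
  generational count error profile.
* ``counts_fit_recovery_panel`` — simulate true generational counts from
  random draws and fit the population model directly to them (best of
  ``n_restarts`` annealing runs), reporting the error profile and the
  per-parameter recovery errors.

Both are deterministic given (n, seed) and scale linearly in n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fcyton import simulate_fcyton
from .fitting import FAST_SCHEDULE, AnnealSchedule, sequential_fit
from .fluorescence import fit_fluorescence_timecourse
from .synthetic import (SCHEDULES, GeneratorConfig, count_error_profile,
                        draw_params, generate_course, param_error)

__all__ = [
    "PanelResult",
    "fluorescence_recovery_panel",
    "counts_fit_recovery_panel",
]


@dataclass
class PanelResult:
    """Aggregate recovery statistics over a panel of generated courses."""

    error_profile: np.ndarray          # per-time-point average normalized % error
    times: np.ndarray
    param_errors: Optional[dict[str, np.ndarray]] = None  # per-course errors

    @property
    def max_error(self) -> float:
        return float(self.error_profile.max())

    def max_error_before(self, t_cut: float) -> float:
        mask = self.times <= t_cut
        return float(self.error_profile[mask].max())

    def median_param_error(self, name: str) -> float:
        if self.param_errors is None:
            raise ValueError("panel carries no parameter errors")
        return float(np.median(self.param_errors[name]))


def _course_seeds(n: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def fluorescence_recovery_panel(
    n_courses: int = 100,
    seed: int = 1,
    schedule: str | Sequence[float] = "ten_point",
    cfg: Optional[GeneratorConfig] = None,
) -> PanelResult:
    """Fit the dye model to noise-free generated histograms, course by course."""
    cfg = cfg or GeneratorConfig(schedule=schedule)
    profiles = []
    for k, cs in enumerate(_course_seeds(n_courses, seed)):
        course = generate_course(cfg=cfg, seed=int(cs))
        fits = fit_fluorescence_timecourse(course.timecourse, seed=int(cs) % 100_000)
        fitted = np.column_stack([w for _, w in fits])
        profiles.append(count_error_profile(course.true_counts.counts, fitted))
    return PanelResult(error_profile=np.stack(profiles).mean(axis=0),
                       times=course.schedule)


def counts_fit_recovery_panel(
    n_courses: int = 50,
    seed: int = 1,
    schedule: str | Sequence[float] = "ten_point",
    n_restarts: int = 8,
    anneal_schedule: Optional[AnnealSchedule] = None,
    cfg: Optional[GeneratorConfig] = None,
) -> PanelResult:
    """Fit the population model to perfect generational counts, per course."""
    cfg = cfg or GeneratorConfig(schedule=schedule)
    times = np.asarray(SCHEDULES[schedule] if isinstance(schedule, str) else schedule,
                       dtype=float)
    sched = anneal_schedule or FAST_SCHEDULE
    profiles = []
    per_param: dict[str, list[float]] = {}
    for k, cs in enumerate(_course_seeds(n_courses, seed)):
        truth_params, _ = draw_params(cfg, seed=int(cs))
        truth = simulate_fcyton(truth_params, times, g_max=cfg.g_max, dt=cfg.dt)
        cand = sequential_fit(truth, n_restarts=n_restarts, seed=int(cs) % 100_000,
                              schedule=sched, g_max=cfg.g_max, dt=cfg.dt)
        fitted = simulate_fcyton(cand.params, times, g_max=cfg.g_max, dt=cfg.dt)
        profiles.append(count_error_profile(truth.counts, fitted.counts))
        for name, err in param_error(truth_params, cand.params).items():
            per_param.setdefault(name, []).append(err)
    return PanelResult(
        error_profile=np.stack(profiles).mean(axis=0),
        times=times,
        param_errors={k: np.asarray(v) for k, v in per_param.items()},
    )
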