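"""End-to-end orchestration: histograms -> fluorescence fit -> repeated
population fitting -> solution quality -> phenotype report.

Also houses the chimeric-parameter analysis (simulating with parameter
groups swapped between two phenotypes) and the tabular exports used to
reproduce the standard visualisations without a plotting dependency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fcyton import (PARAM_NAMES, CountMatrix, FcytonParams,
                     lognormal_from_moments, progressor_fractions,
                     simulate_fcyton)
from .fitting import (AnnealSchedule, SolutionCandidate, integrated_fit,
                      npae, params_from_vector)
from .fluorescence import FluorParams, fit_fluorescence_timecourse, gaussian_bin_matrix
from .io import HistogramTimecourse
from .quality import (SolutionCluster, cluster_solutions, filter_candidates,
                      final_filter, sample_cluster, sensitivity)

__all__ = [
    "RunConfig",
    "PhenotypeReport",
    "PARAM_GROUPS",
    "run_phenotyping",
    "phenotype_timecourse",
    "chimeric_simulate",
    "export_visual_data",
]

log = logging.getLogger(__name__)

#: Named parameter groups for chimeric analysis: the response decision,
#: the later decisions (division destiny), and the two timing blocks.
PARAM_GROUPS: dict[str, tuple[str, ...]] = {
    "F0": ("F0",),
    "F1plus": ("Dmu", "Dsigma"),
    "Tdivs": ("Ediv0", "SDdiv0", "Ediv1", "SDdiv1"),
    "Tdies": ("Edie0", "SDdie0", "Edie1", "SDdie1"),
}


@dataclass
class RunConfig:
    """Declarative configuration of one phenotyping run."""

    hist_csv: Optional[str] = None
    undivided_mean: Optional[Sequence[float]] = None
    g_max: int = 8
    n_restarts: int = 100
    objective_kind: str = "MRSD_plus"
    seed: int = 0
    dt: float = 0.5
    schedule_params: Optional[AnnealSchedule] = None
    final_samples: int = 1000
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**payload)


@dataclass
class PhenotypeReport:
    """Best-fit clusters and everything needed to reproduce them."""

    clusters: list[SolutionCluster]
    fluor: list[FluorParams]
    candidates: list[SolutionCandidate]
    seed: int
    n_restarts: int

    @property
    def best(self) -> SolutionCluster:
        return self.clusters[0]

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for k, cl in enumerate(self.clusters):
            row = {"cluster": k, "n_members": len(cl.members),
                   "median_npae": cl.median_npae, "best_npae": cl.best_npae}
            for i, name in enumerate(PARAM_NAMES):
                lo, hi = cl.ranges[name]
                row[name] = cl.average[i]
                row[f"{name}_lo"] = lo
                row[f"{name}_hi"] = hi
            rows.append(row)
        return pd.DataFrame(rows)


def _npae_fn_for(tc: HistogramTimecourse, fluor: Sequence[FluorParams],
                 g_max: int, dt: float):
    edges = tc.bin_edges
    A_mats = [gaussian_bin_matrix(fp, edges) for fp in fluor]
    data = [h.counts for h in tc.histograms]
    totals = [h.total_cells for h in tc.histograms]
    times = tc.times

    def npae_fn(x: np.ndarray) -> float:
        try:
            cm = simulate_fcyton(params_from_vector(x), times, g_max=g_max, dt=dt)
        except (ValueError, ArithmeticError):
            return 100.0
        model = [A_mats[i] @ cm.counts[:, i] for i in range(len(fluor))]
        return min(100.0, npae(model, data, totals))

    return npae_fn


def phenotype_timecourse(
    tc: HistogramTimecourse,
    cfg: Optional[RunConfig] = None,
) -> PhenotypeReport:
    """Run the full three-step methodology on one histogram time course."""
    from .fitting import sequential_fit

    cfg = cfg or RunConfig()
    log.info("step 1: fluorescence model fitting (%d time points)", len(tc.histograms))
    fluor_fits = fit_fluorescence_timecourse(tc, seed=cfg.seed, g_max=cfg.g_max)
    fluor = [p for p, _ in fluor_fits]
    # classic two-stage estimate: fit the population model to the extracted
    # counts and feed it to the integrated fit as a deterministic warm start
    extracted = CountMatrix(times=tc.times,
                            counts=np.column_stack([w for _, w in fluor_fits]))
    seq = sequential_fit(extracted, n_restarts=4, seed=cfg.seed + 17,
                         schedule=cfg.schedule_params, g_max=cfg.g_max, dt=cfg.dt)
    log.info("step 2: %d integrated population fits", cfg.n_restarts)
    cands = integrated_fit(
        tc, fluor, n_restarts=cfg.n_restarts, objective_kind=cfg.objective_kind,
        seed=cfg.seed, schedule=cfg.schedule_params, g_max=cfg.g_max, dt=cfg.dt,
        warm_starts=[seq.params.to_array()])
    log.info("step 3: quality estimation (best NPAE %.3f)", cands[0].npae)
    kept = filter_candidates(cands)
    npae_fn = _npae_fn_for(tc, fluor, cfg.g_max, cfg.dt)
    for c in kept:
        sensitivity(c, npae_fn)
    clusters = cluster_solutions(kept)
    clusters = final_filter(clusters, npae_fn, n_samples=cfg.final_samples,
                            seed=cfg.seed + 1)
    return PhenotypeReport(clusters=clusters, fluor=fluor, candidates=cands,
                           seed=cfg.seed, n_restarts=cfg.n_restarts)


def run_phenotyping(cfg: RunConfig) -> PhenotypeReport:
    """File-driven entry point: read histograms, run all steps, persist."""
    from .io import read_histogram_csv

    if cfg.hist_csv is None:
        raise ValueError("RunConfig.hist_csv is required")
    path = Path(cfg.hist_csv)
    if not path.exists():
        raise FileNotFoundError(path)
    hists = read_histogram_csv(path)
    if cfg.undivided_mean is None:
        raise ValueError("undivided_mean (one linear intensity per time point) is required")
    tc = HistogramTimecourse(histograms=hists, undivided_mean=cfg.undivided_mean)
    report = phenotype_timecourse(tc, cfg)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.summary_table().to_csv(out / "clusters.csv", index=False)
        manifest = {
            "seed": cfg.seed, "n_restarts": cfg.n_restarts,
            "objective": cfg.objective_kind, "g_max": cfg.g_max, "dt": cfg.dt,
            "n_clusters": len(report.clusters),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def chimeric_simulate(
    a: FcytonParams,
    b: FcytonParams,
    groups: Sequence[str],
    times: Sequence[float],
    g_max: int = 8,
    dt: float = 0.5,
) -> CountMatrix:
    """Simulate a chimera: parameters in ``groups`` copied from b into a.

    Used to dissect which cellular processes (response decision, division
    destiny, division timing, death timing) carry a phenotype difference.
    """
    if not groups:
        raise ValueError("at least one parameter group required")
    unknown = set(groups) - set(PARAM_GROUPS)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}; choose from {sorted(PARAM_GROUPS)}")
    updates = {name: getattr(b, name)
               for grp in groups for name in PARAM_GROUPS[grp]}
    chimera = a.replace(**updates)
    return simulate_fcyton(chimera, times, g_max=g_max, dt=dt)


def export_visual_data(
    cluster: SolutionCluster,
    times: Sequence[float],
    n: int = 250,
    seed: int = 0,
    g_max: int = 8,
    dt: float = 0.5,
    pdf_grid_h: float = 150.0,
) -> dict[str, pd.DataFrame]:
    """Sampled-solution tables for progressor fractions, timing pdfs, counts.

    Returns three frames keyed 'fs' (per-generation progressor fractions per
    sample), 'timing' (the four lognormal pdfs on an hours grid), and
    'trajectories' (generational and total counts over time per sample).
    """
    draws = sample_cluster(cluster, n, seed=seed)
    t_pdf = np.linspace(0.0, pdf_grid_h, 151)
    fs_rows, timing_rows, traj_rows = [], [], []
    for k in range(n):
        p = params_from_vector(draws[k])
        F = progressor_fractions(p.Dmu, p.Dsigma, g_max)
        fs_rows.append({"sample": k, "gen0": p.F0,
                        **{f"gen{g}": F[g] for g in range(1, g_max)}})
        for label, (E, SD) in (("Tdiv0", (p.Ediv0, p.SDdiv0)),
                               ("Tdiv1", (p.Ediv1, p.SDdiv1)),
                               ("Tdie0", (p.Edie0, p.SDdie0)),
                               ("Tdie1", (p.Edie1, p.SDdie1))):
            pdf = lognormal_from_moments(E, SD).pdf(t_pdf)
            peak = pdf.max()
            timing_rows.append({"sample": k, "distribution": label,
                                **{f"t{t:g}": v for t, v in
                                   zip(t_pdf, pdf / peak if peak > 0 else pdf)}})
        cm = simulate_fcyton(p, times, g_max=g_max, dt=dt)
        for i, t in enumerate(cm.times):
            traj_rows.append({"sample": k, "time_h": float(t),
                              **{f"gen{g}": cm.counts[g, i] for g in range(g_max)},
                              "total": float(cm.total[i])})
    return {
        "fs": pd.DataFrame(fs_rows),
        "timing": pd.DataFrame(timing_rows),
        "trajectories": pd.DataFrame(traj_rows),
    }
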