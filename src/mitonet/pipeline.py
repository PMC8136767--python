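"""End-to-end analysis: combined summaries, parameter sweeps, time windows.

Ties the statistics modules together the way the study design uses them:
one combined physical + network summary per trajectory set (network
statistics at the final cumulative frame, physical statistics over all
frames), sweeps over many parameterizations for the spread-vs-connectivity
tradeoff analysis, and time-windowed re-analysis for comparing systems at
matched observation horizons.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from . import encounter_network as enet
from . import physical_stats as pstats
from .simulator import SimulationParams, get_preset, run_simulation
from .trajectory_io import TrackSet

logger = logging.getLogger(__name__)


@dataclass
class SummaryRecord:
    """One row of the experiment-vs-theory comparison table."""

    label: str
    duration_s: float
    n_tracks: int
    mean_speed_um_s: float
    mean_ch_um2: float
    inter_mito_mean_um: float
    inter_mito_cv: float
    diffusion_estimate_um2_s: float | None
    mean_association_time_s: float | None
    n_nodes: int
    mean_degree: float
    degree_cv: float
    n_components: int
    largest_component_fraction: float
    efficiency_unweighted: float
    efficiency_weighted: float | None
    percolation_threshold_frame: int | None
    degree_drop: float | None
    avg_connected_neighbours: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize(tracks: TrackSet,
              threshold_um: float = enet.DEFAULT_THRESHOLD_UM,
              label: str | None = None, rng: int | None = 0,
              max_lag_s: float = 10.0) -> SummaryRecord:
    """Full physical + network summary of one TrackSet.

    Network statistics are taken from the cumulative encounter network at
    the final frame (singletons included); physical statistics pool all
    frames.  ``rng`` seeds the stochastic degree-drop walks.
    """
    series = enet.build_encounter_series(tracks, threshold_um)
    phys = pstats.summarize_physical(tracks, series, max_lag_s=max_lag_s)
    net = enet.summarize_network(series, rng=np.random.default_rng(rng))
    assoc = phys.association_time_samples_s
    return SummaryRecord(
        label=label if label is not None else (tracks.provenance or "tracks"),
        duration_s=tracks.duration_s,
        n_tracks=tracks.n_tracks,
        mean_speed_um_s=phys.mean_speed_um_s,
        mean_ch_um2=phys.mean_convex_hull_um2,
        inter_mito_mean_um=phys.inter_mito_mean_um,
        inter_mito_cv=phys.inter_mito_cv,
        diffusion_estimate_um2_s=phys.diffusion_estimate_um2_s,
        mean_association_time_s=float(np.mean(assoc)) if assoc is not None and len(assoc) else None,
        n_nodes=net.n_nodes,
        mean_degree=net.mean_degree,
        degree_cv=net.degree_cv,
        n_components=net.n_components,
        largest_component_fraction=net.largest_component_fraction,
        efficiency_unweighted=net.efficiency_unweighted,
        efficiency_weighted=net.efficiency_weighted,
        percolation_threshold_frame=net.percolation_threshold_frame,
        degree_drop=net.degree_drop,
        avg_connected_neighbours=net.avg_connected_neighbours)


def run_sweep(param_list, seeds=(0,),
              threshold_um: float = enet.DEFAULT_THRESHOLD_UM) -> pd.DataFrame:
    """One summary row per (parameterization, seed).

    ``param_list`` is a sequence of ``(label, SimulationParams)`` pairs or
    bare SimulationParams.  A failed run is recorded with its error message
    and the sweep continues.
    """
    if not len(param_list):
        raise ValueError("run_sweep needs at least one parameterization")
    rows = []
    for entry in param_list:
        label, params = entry if isinstance(entry, tuple) else (None, entry)
        for seed in seeds:
            p = replace(params, seed=int(seed))
            run_label = f"{label or 'params'}_s{seed}"
            try:
                tracks = run_simulation(p, label=run_label)
                rec = summarize(tracks, threshold_um, label=run_label,
                                rng=int(seed))
                row = rec.as_dict()
                row.update(param_label=label or "params", seed=int(seed),
                           status="ok", error="")
            except Exception as exc:  # keep sweeping, record the failure
                logger.warning("sweep run %s failed: %s", run_label, exc)
                row = dict(label=run_label, param_label=label or "params",
                           seed=int(seed), status="error", error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def default_sweep_params() -> list[tuple[str, SimulationParams]]:
    """The standard 12-parameterization sweep for the tradeoff analysis.

    The nine named presets (four illustrative systems, two family
    representatives, three limit-case scenarios) plus three fixed vectors
    representative of the random-parameterization family priors, chosen to
    span sparse/slow through dense/fast populations.
    """
    sweep = [(name, get_preset(name))
             for name in ("NM9", "NM10", "NM11", "NM12", "ST", "BM",
                          "S1", "S5", "S7")]
    sweep += [
        ("R_sparse", SimulationParams(n_mito=20, n_cyt=3, D=0.30, k_out=0.086,
                                      d_cyt=0.85, k_on=0.85, k_off=0.43,
                                      k_cyt=0.85)),
        ("R_dense", SimulationParams(n_mito=150, n_cyt=0, D=0.20, k_out=0.086)),
        ("R_mid", SimulationParams(n_mito=60, n_cyt=8, D=0.60, k_out=0.086,
                                   d_cyt=0.85, k_on=0.85, k_off=0.43,
                                   k_cyt=0.85)),
    ]
    return sweep


def tradeoff_correlations(table: pd.DataFrame) -> dict:
    """Spearman rank correlations behind the spread-vs-connectivity analysis.

    * spacing vs connectivity (InterMitoMean vs mean degree) — expected
      negative: well-connected populations sit closer together;
    * coverage vs connectivity (MeanCH vs mean degree) — expected positive:
      organelles sweeping larger areas meet more partners;
    * degree CV vs mean degree — expected negative: sparsely connected
      networks are noisier.
    """
    ok = table[table["status"] == "ok"] if "status" in table else table
    out = {}
    for name, (a, b) in {
        "spacing_vs_degree": ("inter_mito_mean_um", "mean_degree"),
        "coverage_vs_degree": ("mean_ch_um2", "mean_degree"),
        "degree_cv_vs_degree": ("degree_cv", "mean_degree"),
    }.items():
        sub = ok[[a, b]].dropna()
        rho, p = spearmanr(sub[a], sub[b])
        out[name] = {"spearman_rho": float(rho), "p_value": float(p),
                     "n": int(len(sub))}
    return out


@dataclass
class WindowedRecord:
    """Connectivity and spacing of one TrackSet within one time window."""

    label: str
    window_s: float
    mean_degree: float
    inter_mito_mean_um: float


def windowed_compare(track_sets: dict[str, TrackSet], window_lengths_s,
                     threshold_um: float = enet.DEFAULT_THRESHOLD_UM,
                     ) -> pd.DataFrame:
    """Rebuild encounter networks within growing windows anchored at start.

    For each TrackSet and each window length, only frames within
    ``[t0, t0 + window]`` enter both the network (mean degree at the last
    in-window frame) and the nearest-neighbour spacing.  Windows must be
    ascending and no longer than the capture duration.
    """
    windows = list(window_lengths_s)
    if windows != sorted(windows):
        raise ValueError("window lengths must be sorted ascending")
    rows = []
    for label, tracks in track_sets.items():
        if windows and windows[-1] > tracks.duration_s:
            raise ValueError(
                f"window {windows[-1]} s exceeds capture duration "
                f"{tracks.duration_s} s of {label!r}")
        for win in windows:
            sub = tracks.time_window(win)
            series = enet.build_encounter_series(sub, threshold_um)
            _, mean_deg, _ = enet.degree_statistics(series)
            nn = pstats.nearest_neighbour_distances(sub)["nn_um"].dropna()
            rows.append(WindowedRecord(
                label=label, window_s=float(win), mean_degree=mean_deg,
                inter_mito_mean_um=float(nn.mean()) if len(nn) else float("nan")))
    return pd.DataFrame([asdict(r) for r in rows])


def weighted_unweighted_check(table: pd.DataFrame) -> dict:
    """Correlation between unweighted and association-weighted efficiency.

    A tight positive correlation indicates the unweighted networks already
    capture the structure the association-time weighting would add.
    Requires at least 5 records; constant columns are flagged undefined.
    """
    cols = ["efficiency_unweighted", "efficiency_weighted"]
    sub = table[cols].dropna()
    if len(sub) < 5:
        raise ValueError(f"need at least 5 records, got {len(sub)}")
    x, y = sub[cols[0]].to_numpy(), sub[cols[1]].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("weighted_unweighted_check: constant column, undefined")
        return {"pearson_r": float("nan"), "spearman_rho": float("nan"),
                "n": int(len(sub))}
    return {"pearson_r": float(pearsonr(x, y).statistic),
            "spearman_rho": float(spearmanr(x, y).statistic),
            "n": int(len(sub))}
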