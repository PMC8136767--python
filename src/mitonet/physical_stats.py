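"""Per-organelle physical statistics of a TrackSet.

Speed, turning angle, convex-hull coverage, nearest-neighbour spacing,
MSD-based diffusion estimation and pairwise association times.  All
quantities are metric (um, s); frame indices never enter a rate — elapsed
time does, so tracker gaps are handled correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress

from .encounter_network import EncounterNetworkSeries, association_times_from_series
from .trajectory_io import TrackSet

logger = logging.getLogger(__name__)


def instantaneous_speeds(tracks: TrackSet) -> np.ndarray:
    """Per-step speeds (um/s): Euclidean displacement over elapsed time.

    One sample per consecutive point pair within a trajectory.  Across a
    tracker gap the *actual* elapsed time divides the displacement — speed
    is a rate, not a per-frame difference.  Returns an empty (flagged)
    array when no trajectory has two points.
    """
    samples = []
    for _, g in tracks.trajectories():
        if len(g) < 2:
            continue
        xy = g[["x_um", "y_um"]].to_numpy(float)
        dt = np.diff(g["time_s"].to_numpy(float))
        disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        samples.append(disp / dt)
    if not samples:
        logger.info("instantaneous_speeds: no trajectory with >= 2 points")
        return np.empty(0)
    return np.concatenate(samples)


def motion_angles(tracks: TrackSet) -> np.ndarray:
    """Turning angles (degrees) over consecutive frame triplets.

    For points p1, p2, p3 the statistic is 180 - (180/pi) *
    arccos(a.b/|a||b|) with a = p1 - p2 and b = p3 - p2 (the two rays from
    the middle point): 0 deg is constant direction, 180 deg an exact
    reversal.  Triplets containing a zero-length step are skipped (the
    cosine is undefined) with a logged count.
    """
    samples = []
    skipped = 0
    for _, g in tracks.trajectories():
        if len(g) < 3:
            continue
        xy = g[["x_um", "y_um"]].to_numpy(float)
        a = xy[:-2] - xy[1:-1]
        b = xy[2:] - xy[1:-1]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        ok = (na > 0) & (nb > 0)
        skipped += int((~ok).sum())
        cosang = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
        ang = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        samples.append(ang)
    if skipped:
        logger.info("motion_angles: skipped %d triplets with zero-length steps",
                    skipped)
    return np.concatenate(samples) if samples else np.empty(0)


def convex_hull_areas(tracks: TrackSet) -> pd.Series:
    """Convex-hull area (um^2) swept out by each trajectory of >= 3 points.

    The hull is the polygon around the furthest-reaching points of the
    trajectory; degenerate (collinear or coincident) point sets get area 0.
    Shorter trajectories are excluded from the output.
    """
    areas = {}
    for tid, g in tracks.trajectories():
        if len(g) < 3:
            continue
        xy = g[["x_um", "y_um"]].to_numpy(float)
        try:
            areas[tid] = float(ConvexHull(xy).volume)  # 2D: volume == area
        except QhullError:
            areas[tid] = 0.0
    return pd.Series(areas, dtype=float)


def nearest_neighbour_distances(tracks: TrackSet) -> pd.DataFrame:
    """Distance (um) from each organelle to its nearest neighbour, per frame.

    Returns a tidy frame ``(frame, track_id, nn_um)``.  An organelle alone
    in its frame has no neighbour: its distance is NaN (flagged) and is
    excluded from any downstream mean.
    """
    rows = []
    for frame, g in tracks.data.groupby("frame", sort=True):
        ids = list(g["track_id"])
        if len(ids) == 1:
            rows.append((int(frame), ids[0], np.nan))
            continue
        d = squareform(pdist(g[["x_um", "y_um"]].to_numpy(float)))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        rows.extend((int(frame), tid, float(v)) for tid, v in zip(ids, nn))
    return pd.DataFrame(rows, columns=["frame", "track_id", "nn_um"])


# ---------------------------------------------------------------------------
# Diffusion from mean-squared displacement
# ---------------------------------------------------------------------------

def mean_squared_displacement(tracks: TrackSet, track_subset=None,
                              max_lag_s: float = 10.0):
    """Time-averaged MSD per lag, averaged over the selected tracks.

    Lags are multiples of the frame interval up to ``max_lag_s``.  Only
    tracks with no internal gaps and enough points contribute at a given
    lag.  Returns ``(lags_s, msd_um2)`` with empty-lag entries dropped.
    """
    dt = tracks.frame_interval_s
    max_k = int(np.floor(max_lag_s / dt))
    if max_k < 1:
        raise ValueError("max_lag_s shorter than one frame interval")
    subset = set(track_subset) if track_subset is not None else None
    per_lag = [[] for _ in range(max_k)]
    for tid, g in tracks.trajectories():
        if subset is not None and tid not in subset:
            continue
        frames = g["frame"].to_numpy()
        if len(frames) < 2 or np.any(np.diff(frames) != 1):
            continue  # gap-free tracks only: lags must be uniform
        xy = g[["x_um", "y_um"]].to_numpy(float)
        for k in range(1, min(max_k, len(xy) - 1) + 1):
            d2 = np.sum((xy[k:] - xy[:-k]) ** 2, axis=1)
            per_lag[k - 1].append(d2.mean())
    lags, msd = [], []
    for k, vals in enumerate(per_lag, start=1):
        if vals:
            lags.append(k * dt)
            msd.append(float(np.mean(vals)))
    return np.asarray(lags), np.asarray(msd)


def estimate_diffusion(tracks: TrackSet, track_subset=None,
                       max_lag_s: float = 10.0) -> float:
    """Diffusion coefficient D (um^2/s) from the slope of MSD over lag time.

    Ordinary least squares of MSD against lag (intercept left free, since
    localisation noise offsets MSD), D = slope / 4 for 2D motion.  Requires
    at least two populated lags.
    """
    lags, msd = mean_squared_displacement(tracks, track_subset, max_lag_s)
    if len(lags) < 2:
        raise ValueError("estimate_diffusion needs at least 2 populated lags")
    slope = linregress(lags, msd).slope
    return float(slope / 4.0)


def diffusive_candidates(tracks: TrackSet, max_lag_s: float = 10.0,
                         exponent_threshold: float = 1.2) -> list:
    """Tracks whose MSD scaling exponent suggests diffusive (not ballistic) motion.

    Fits the log-log slope alpha of the per-track MSD; pure diffusion gives
    alpha ~ 1, ballistic runs alpha ~ 2.  Tracks with alpha below the
    threshold are flagged as candidates for diffusion estimation (the final
    subset choice stays with the caller).
    """
    out = []
    for tid, _ in tracks.trajectories():
        try:
            lags, msd = mean_squared_displacement(tracks, [tid], max_lag_s)
        except ValueError:
            continue
        pos = msd > 0
        if pos.sum() < 2:
            continue
        alpha = linregress(np.log(lags[pos]), np.log(msd[pos])).slope
        if alpha < exponent_threshold:
            out.append(tid)
    return out


def association_times(series: EncounterNetworkSeries, mode: str = "total") -> dict:
    """Seconds each organelle pair spent colocalized (see encounter_network).

    ``mode='total'`` sums separate colocalization episodes; ``'longest'``
    keeps only the longest contiguous one.  Pairs never colocalized are
    absent (they are not zero-valued samples).
    """
    return association_times_from_series(series, mode=mode)


# ---------------------------------------------------------------------------
# Aggregate
# ---------------------------------------------------------------------------

@dataclass
class PhysicalSummary:
    """Aggregated physical statistics of one TrackSet."""

    mean_speed_um_s: float
    speed_samples: np.ndarray
    angle_samples_deg: np.ndarray
    convex_hull_areas_um2: pd.Series
    mean_convex_hull_um2: float      # MeanCH
    nn_distances: pd.DataFrame
    inter_mito_mean_um: float        # InterMitoMean
    inter_mito_cv: float
    diffusion_estimate_um2_s: float | None
    association_time_samples_s: np.ndarray | None


def summarize_physical(tracks: TrackSet,
                       series: EncounterNetworkSeries | None = None,
                       max_lag_s: float = 10.0) -> PhysicalSummary:
    """Compute every PhysicalSummary field; association times need a series."""
    speeds = instantaneous_speeds(tracks)
    angles = motion_angles(tracks)
    hulls = convex_hull_areas(tracks)
    nn = nearest_neighbour_distances(tracks)
    nn_valid = nn["nn_um"].dropna()
    imm = float(nn_valid.mean()) if len(nn_valid) else float("nan")
    icv = float(nn_valid.std(ddof=0) / imm) if len(nn_valid) and imm > 0 else float("nan")
    try:
        dhat = estimate_diffusion(tracks, max_lag_s=max_lag_s)
    except ValueError:
        dhat = None
    assoc = None
    if series is not None:
        assoc = np.asarray(sorted(association_times(series).values()), float)
    return PhysicalSummary(
        mean_speed_um_s=float(speeds.mean()) if len(speeds) else float("nan"),
        speed_samples=speeds, angle_samples_deg=angles,
        convex_hull_areas_um2=hulls,
        mean_convex_hull_um2=float(hulls.mean()) if len(hulls) else float("nan"),
        nn_distances=nn, inter_mito_mean_um=imm, inter_mito_cv=icv,
        diffusion_estimate_um2_s=dhat, association_time_samples_s=assoc)
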