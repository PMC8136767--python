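"""Controlled synthetic trajectory generators.

The simulator produces *realistic* inputs; this module produces *controlled*
ones — deterministic geometries with hand-checkable statistics (lines,
reversals, squares, static lattices) and stochastic populations whose
ground truth is known (pure Brownian walkers for the diffusion estimator,
mixed ballistic/diffusive populations whose per-track speeds span at least
an order of magnitude, as in the experimental videos).  Every fixture is a
valid input to every pipeline stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trajectory_io import COLUMNS, TrackSet

DETERMINISTIC_KINDS = ("line", "reversal", "square", "lattice")


def _trackset(rows, dt, **meta) -> TrackSet:
    df = pd.DataFrame(rows, columns=COLUMNS)
    return TrackSet(df, frame_interval_s=dt, **meta)


def make_deterministic_track(kind: str, n_frames: int = 5, step_um: float = 1.0,
                             side_um: float = 2.0, shape: tuple = (3, 3),
                             spacing_um: float = 3.0, dt: float = 1.0) -> TrackSet:
    """Exact, hand-checkable trajectories.

    * ``line``: one track moving +x by ``step_um`` per frame (all angles 0).
    * ``reversal``: one track bouncing between x=0 and x=``step_um``
      (all angles 180).
    * ``square``: one track walking the corners of a square of ``side_um``
      (hull area = side^2).
    * ``lattice``: a static grid of ``shape`` tracks at ``spacing_um``
      (all nearest-neighbour distances = spacing).
    """
    rows = []
    if kind == "line":
        for f in range(n_frames):
            rows.append(("t0", f, f * dt, f * step_um, 0.0))
    elif kind == "reversal":
        for f in range(n_frames):
            rows.append(("t0", f, f * dt, step_um * (f % 2), 0.0))
    elif kind == "square":
        corners = [(0.0, 0.0), (side_um, 0.0), (side_um, side_um), (0.0, side_um)]
        for f in range(max(n_frames, 4)):
            x, y = corners[f % 4]
            rows.append(("t0", f, f * dt, x, y))
    elif kind == "lattice":
        nx_, ny_ = shape
        for f in range(n_frames):
            for i in range(nx_):
                for j in range(ny_):
                    rows.append((f"t{i}_{j}", f, f * dt,
                                 i * spacing_um, j * spacing_um))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {DETERMINISTIC_KINDS}")
    return _trackset(rows, dt, provenance=f"fixture:{kind}")


def make_brownian_tracks(n: int, D: float, n_frames: int, dt: float = 1.0,
                         region=(30.0, 100.0), seed: int = 0) -> TrackSet:
    """Independent Gaussian random walks with known diffusion coefficient.

    Per-axis step variance is exactly 2*D*dt; walkers reflect off the
    region boundary (reflection keeps the sampled diffusion unbiased,
    unlike the simulator's truncation rule).  Ground-truth oracle for the
    MSD estimator.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed)
    w, h = region
    start = rng.uniform([0, 0], [w, h], (n, 2))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), (n_frames - 1, n, 2)) \
        if n_frames > 1 else np.zeros((0, n, 2))
    paths = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    # reflect into [0, w] x [0, h]: fold the unbounded path
    for axis, hi in ((0, w), (1, h)):
        p = np.mod(paths[..., axis], 2 * hi)
        paths[..., axis] = np.where(p > hi, 2 * hi - p, p)
    rows = []
    for f in range(n_frames):
        for i in range(n):
            rows.append((f"b{i}", f, f * dt, paths[f, i, 0], paths[f, i, 1]))
    return _trackset(rows, dt, region_width_um=w, region_height_um=h,
                     provenance="fixture:brownian")


def make_mixed_population(n: int = 60, ballistic_fraction: float = 0.5,
                          speed_range_um_s=(0.05, 1.0), n_frames: int = 100,
                          dt: float = 1.0, region=(30.0, 100.0),
                          turn_prob: float = 0.1, boundary_flux: bool = False,
                          flux_prob: float = 0.01, seed: int = 0) -> TrackSet:
    """Mixture of ballistic and diffusive movers with heterogeneous speeds.

    Per-track speeds are log-uniform over ``speed_range_um_s`` (spanning at
    least one order of magnitude by default, as observed experimentally).
    Ballistic movers run straight with Poisson turn events; diffusive
    movers take isotropic Gaussian steps of matching mean step length; all
    reflect at the region boundary.  With ``boundary_flux`` tracks can
    terminate near the edge and re-enter as *fresh* track ids, mimicking
    organelles leaving and entering the imaged plane.
    """
    if not 0 <= ballistic_fraction <= 1:
        raise ValueError("ballistic_fraction must lie in [0, 1]")
    lo, hi = speed_range_um_s
    if not 0 < lo <= hi:
        raise ValueError("speed range must be positive and ordered")
    rng = np.random.default_rng(seed)
    w, h = region
    rows = []
    next_id = 0

    def new_agent():
        nonlocal next_id
        tid = f"m{next_id}"
        next_id += 1
        speed = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        ballistic = rng.random() < ballistic_fraction
        pos = rng.uniform([0, 0], [w, h])
        theta = rng.uniform(0, 2 * np.pi)
        return dict(tid=tid, speed=speed, ballistic=ballistic,
                    pos=pos, theta=theta)

    agents = [new_agent() for _ in range(n)]
    edge_band = 2.0
    for f in range(n_frames):
        for k in range(len(agents)):
            a = agents[k]
            rows.append((a["tid"], f, f * dt, a["pos"][0], a["pos"][1]))
            if a["ballistic"]:
                if rng.random() < turn_prob:
                    a["theta"] = rng.uniform(0, 2 * np.pi)
                step_vec = a["speed"] * dt * np.array(
                    [np.cos(a["theta"]), np.sin(a["theta"])])
            else:
                # isotropic Gaussian step whose mean length equals speed*dt
                sigma = a["speed"] * dt / np.sqrt(np.pi / 2)
                step_vec = rng.normal(0.0, sigma, 2)
            p = a["pos"] + step_vec
            for axis, hi_ in ((0, w), (1, h)):
                if p[axis] < 0:
                    p[axis] = -p[axis]
                    a["theta"] = rng.uniform(0, 2 * np.pi)
                elif p[axis] > hi_:
                    p[axis] = 2 * hi_ - p[axis]
                    a["theta"] = rng.uniform(0, 2 * np.pi)
            a["pos"] = p
            near_edge = (p[0] < edge_band or p[0] > w - edge_band
                         or p[1] < edge_band or p[1] > h - edge_band)
            if boundary_flux and near_edge and rng.random() < flux_prob:
                agents[k] = new_agent()  # leaves; a fresh id enters
    return _trackset(rows, dt, region_width_um=w, region_height_um=h,
                     provenance="fixture:mixed_population")
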