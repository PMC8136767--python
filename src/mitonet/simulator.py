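"""Agent-based umbrella model of fragmented mitochondrial dynamics.

``n_mito`` point agents move in a rectangular 2D cell (default 30 x 100 um,
typical hypocotyl-cell dimensions).  The model unifies, in one parameter
vector, every transport mechanism considered for plant chondriome motion:

* free diffusion with coefficient ``D`` (um^2/s) when not attached;
* ``n_cyt`` randomly placed linear cytoskeletal strands; agents within
  ``d_cyt`` of a strand attach/detach via Poisson rates ``k_on``/``k_off``
  and, while attached, run parallel to the strand at speed ``k_cyt``,
  switching strands when passing near an intersection;
* contact slowdown: agents within ``d_mito`` of another agent have their
  step scaled by ``k_mito`` (1 = no effect);
* a deliberately simple hydrodynamic coupling ``F_hydro`` that adds the
  inverse-distance-weighted average of the other agents' previous
  velocities (a caricature of cytoplasmic streaming, not a fluid solver);
* boundary turnover: within ``d_edge`` of the cell edge agents vanish at
  rate ``k_out`` (motion out of the imaged cytosol plane) and are replaced
  by a *new* agent — a fresh track identity — at a random point of the
  boundary region, keeping the agent count constant.

Steps that would leave the cell are truncated at the boundary.  A burn-in
period (default 1000 steps) is discarded before capture so statistics do
not reflect the uniform initial condition.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .trajectory_io import COLUMNS, TrackSet

_RATE_FIELDS = ("k_on", "k_off", "k_out")


@dataclass
class SimulationParams:
    """Full parameter vector of the umbrella model.

    Rates are per-second hazards, converted internally to per-step
    probabilities ``1 - exp(-k * dt)``; distances in um, speeds in um/s.
    """

    n_mito: int = 100
    n_cyt: int = 0
    D: float = 0.15               # diffusion coefficient, um^2/s
    k_on: float = 0.0             # strand attachment rate, 1/s
    k_off: float = 0.0            # strand detachment rate, 1/s
    k_cyt: float = 0.0            # on-strand speed, um/s
    k_out: float = 0.0            # boundary disappearance rate, 1/s
    k_mito: float = 1.0           # contact motion scaling (1 = none)
    d_mito: float = 1.6           # contact interaction range, um
    d_cyt: float = 0.85           # strand capture distance, um
    d_edge: float = 4.0           # boundary region width, um
    F_hydro: float = 0.0          # hydrodynamic coupling (0 = off)
    cell_x: float = 30.0          # cell width, um
    cell_y: float = 100.0         # cell height, um
    dt: float = 1.0               # time step, s
    n_frames: int = 230           # captured frames (230 s horizon at dt=1)
    burn_in: int = 1000           # discarded initialisation steps
    switch_prob: float = 0.5      # strand-switch probability at intersections
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mito < 0 or self.n_cyt < 0 or self.n_frames < 0 or self.burn_in < 0:
            raise ValueError("counts must be non-negative")
        if not (self.dt > 0 and self.cell_x > 0 and self.cell_y > 0):
            raise ValueError("dt and cell dimensions must be positive")
        for name in ("D", "k_on", "k_off", "k_cyt", "k_out", "k_mito",
                     "d_mito", "d_cyt", "d_edge", "F_hydro"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.switch_prob <= 1:
            raise ValueError("switch_prob must lie in [0, 1]")

    def step_probability(self, rate_name: str) -> float:
        """Per-step probability 1 - exp(-k * dt) of the named rate."""
        if rate_name not in _RATE_FIELDS:
            raise ValueError(f"unknown rate {rate_name!r}")
        return float(-np.expm1(-getattr(self, rate_name) * self.dt))

    # JSON config mirrors the dataclass field-for-field.
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationParams":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Cytoskeletal strands
# ---------------------------------------------------------------------------

@dataclass
class CytoskeletalStrand:
    """A line segment clipped to the cell rectangle."""

    p0: np.ndarray
    p1: np.ndarray

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, float)
        self.p1 = np.asarray(self.p1, float)
        if not np.linalg.norm(self.p1 - self.p0) > 0:
            raise ValueError("strand must have positive length")

    @property
    def direction(self) -> np.ndarray:
        v = self.p1 - self.p0
        return v / np.linalg.norm(v)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))


def make_strands(params: SimulationParams, rng) -> list[CytoskeletalStrand]:
    """``n_cyt`` random lines: uniform interior point, uniform orientation,
    extended both ways and clipped to the cell rectangle."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    strands = []
    for _ in range(params.n_cyt):
        point = rng.uniform([0, 0], [params.cell_x, params.cell_y])
        theta = rng.uniform(0, np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        t_lo, t_hi = _clip_line(point, u, params.cell_x, params.cell_y)
        strands.append(CytoskeletalStrand(point + t_lo * u, point + t_hi * u))
    return strands


def _clip_line(point, u, cell_x, cell_y):
    """Parameter range [t_lo, t_hi] of line point + t*u inside the rectangle."""
    t_lo, t_hi = -np.inf, np.inf
    for axis, hi in ((0, cell_x), (1, cell_y)):
        if abs(u[axis]) < 1e-12:
            continue
        a = (0.0 - point[axis]) / u[axis]
        b = (hi - point[axis]) / u[axis]
        t_lo = max(t_lo, min(a, b))
        t_hi = min(t_hi, max(a, b))
    return t_lo, t_hi


def _segment_intersections(strands):
    """Per-strand list of (point, other_strand_index) crossings."""
    crossings = [[] for _ in strands]
    for i in range(len(strands)):
        for j in range(i + 1, len(strands)):
            p = _intersect(strands[i], strands[j])
            if p is not None:
                crossings[i].append((p, j))
                crossings[j].append((p, i))
    return crossings


def _cross2(a, b):
    return a[0] * b[1] - a[1] * b[0]


def _intersect(s1, s2):
    p, r = s1.p0, s1.p1 - s1.p0
    q, s = s2.p0, s2.p1 - s2.p0
    denom = _cross2(r, s)
    if abs(denom) < 1e-12:
        return None
    t = _cross2(q - p, s) / denom
    u = _cross2(q - p, r) / denom
    if 0 <= t <= 1 and 0 <= u <= 1:
        return p + t * r
    return None


def _point_segment_distance(points, strand):
    """Distances from (n, 2) points to one segment."""
    v = strand.p1 - strand.p0
    L2 = v @ v
    t = np.clip((points - strand.p0) @ v / L2, 0.0, 1.0)
    proj = strand.p0 + t[:, None] * v
    return np.linalg.norm(points - proj, axis=1)


# ---------------------------------------------------------------------------
# State and stepping
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Mutable agent/strand state; advanced in place by :func:`step`."""

    positions: np.ndarray        # (n, 2)
    velocities: np.ndarray       # previous-step velocity, (n, 2)
    attached: np.ndarray         # strand index or -1
    direction: np.ndarray        # +-1 travel direction along strand
    ids: np.ndarray              # unique agent ids (fresh on replacement)
    next_id: int
    strands: list
    crossings: list
    frame: int
    rng: np.random.Generator


def initialize_state(params: SimulationParams, rng=None) -> SimulationState:
    rng = np.random.default_rng(params.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    strands = make_strands(params, rng)
    n = params.n_mito
    return SimulationState(
        positions=rng.uniform([0, 0], [params.cell_x, params.cell_y], (n, 2)),
        velocities=np.zeros((n, 2)),
        attached=np.full(n, -1, dtype=int),
        direction=np.ones(n, dtype=int),
        ids=np.arange(n, dtype=int),
        next_id=n,
        strands=strands,
        crossings=_segment_intersections(strands),
        frame=0,
        rng=rng)


def _in_boundary_region(pos, params):
    x, y = pos[:, 0], pos[:, 1]
    d = params.d_edge
    return ((x < d) | (x > params.cell_x - d)
            | (y < d) | (y > params.cell_y - d))


def _sample_boundary_point(params, rng):
    # Rejection sampling: the boundary band is a large fraction of the
    # default cell, so this converges in a couple of draws.
    while True:
        p = rng.uniform([0, 0], [params.cell_x, params.cell_y])
        if _in_boundary_region(p[None, :], params)[0]:
            return p


def step(state: SimulationState, params: SimulationParams) -> SimulationState:
    """Advance the state by one time step ``dt``.

    Rule order: attach/detach -> motion (diffusive or on-strand) -> contact
    scaling -> hydrodynamic coupling -> boundary truncation -> strand
    switching -> boundary turnover.
    """
    rng = state.rng
    n = params.n_mito
    pos = state.positions
    dt = params.dt

    # 1) attach / detach (Poisson hazards -> per-step probabilities)
    if state.strands:
        p_on = params.step_probability("k_on")
        p_off = params.step_probability("k_off")
        att = state.attached >= 0
        if p_off > 0 and att.any():
            detach = att & (rng.random(n) < p_off)
            state.attached[detach] = -1
        if p_on > 0:
            free = state.attached < 0
            if free.any():
                dists = np.stack([_point_segment_distance(pos[free], s)
                                  for s in state.strands], axis=1)
                nearest = np.argmin(dists, axis=1)
                near = dists[np.arange(len(nearest)), nearest] <= params.d_cyt
                attach = near & (rng.random(near.shape[0]) < p_on)
                idx = np.flatnonzero(free)[attach]
                state.attached[idx] = nearest[attach]
                state.direction[idx] = rng.choice([-1, 1], size=len(idx))

    # 2) motion
    disp = np.zeros_like(pos)
    free = state.attached < 0
    if free.any() and params.D > 0:
        sigma = np.sqrt(2.0 * params.D * dt)
        disp[free] = rng.normal(0.0, sigma, (int(free.sum()), 2))
    bound = ~free
    if bound.any() and params.k_cyt > 0:
        dirs = np.stack([state.strands[s].direction for s in state.attached[bound]])
        disp[bound] = params.k_cyt * dt * state.direction[bound, None] * dirs

    # 3) contact scaling of this step's displacement
    if params.k_mito != 1.0 and params.d_mito > 0 and n > 1:
        d = squareform(pdist(pos))
        np.fill_diagonal(d, np.inf)
        in_contact = (d <= params.d_mito).any(axis=1)
        disp[in_contact] *= params.k_mito

    # 4) hydrodynamic coupling: inverse-distance-weighted mean of the other
    #    agents' previous velocities (r floored at 0.1 um to avoid blow-up)
    if params.F_hydro > 0 and n > 1:
        r = squareform(pdist(pos))
        np.fill_diagonal(r, np.inf)
        w = 1.0 / np.maximum(r, 0.1)
        np.fill_diagonal(w, 0.0)
        drift = (w @ state.velocities) / (n - 1)
        disp += params.F_hydro * drift * dt

    # 5) boundary truncation
    new_pos = np.clip(pos + disp,
                      [0.0, 0.0], [params.cell_x, params.cell_y])
    state.velocities = (new_pos - pos) / dt
    state.positions = new_pos

    # strand switching at intersections passed during on-strand motion
    if state.strands and bound.any() and params.switch_prob > 0:
        for i in np.flatnonzero(bound):
            s = state.attached[i]
            for point, other in state.crossings[s]:
                if np.linalg.norm(state.positions[i] - point) <= params.d_cyt:
                    if rng.random() < params.switch_prob:
                        state.attached[i] = other
                        state.direction[i] = rng.choice([-1, 1])
                    break

    # 6) boundary turnover: disappear at rate k_out, replace with a fresh
    #    agent (new track identity) inside the boundary region
    if params.k_out > 0:
        p_out = params.step_probability("k_out")
        edge = _in_boundary_region(state.positions, params)
        gone = edge & (rng.random(n) < p_out)
        for i in np.flatnonzero(gone):
            state.positions[i] = _sample_boundary_point(params, rng)
            state.velocities[i] = 0.0
            state.attached[i] = -1
            state.ids[i] = state.next_id
            state.next_id += 1

    state.frame += 1
    return state


def run_simulation(params: SimulationParams, label: str = "simulation") -> TrackSet:
    """Burn in, then capture ``n_frames`` frames as a TrackSet.

    Each agent identity becomes a track; replacements at the boundary start
    new tracks, so track count generally exceeds ``n_mito``.  Identical
    parameters and seed give bit-identical output.
    """
    state = initialize_state(params)
    for _ in range(params.burn_in):
        step(state, params)
    ids, frames, xs, ys = [], [], [], []
    for f in range(params.n_frames):
        ids.append(state.ids.copy())
        frames.append(np.full(params.n_mito, f, dtype=int))
        xs.append(state.positions[:, 0].copy())
        ys.append(state.positions[:, 1].copy())
        if f < params.n_frames - 1:
            step(state, params)
    if params.n_frames == 0 or params.n_mito == 0:
        df = pd.DataFrame({c: [] for c in COLUMNS})
    else:
        frame = np.concatenate(frames)
        df = pd.DataFrame({
            "track_id": np.concatenate(ids),
            "frame": frame,
            "time_s": frame * params.dt,
            "x_um": np.concatenate(xs),
            "y_um": np.concatenate(ys)})
    return TrackSet(df, frame_interval_s=params.dt,
                    region_width_um=params.cell_x, region_height_um=params.cell_y,
                    provenance=label)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_catalogue() -> dict[str, SimulationParams]:
    """Named parameterizations of the illustrative and family systems.

    NM9-NM12 are the four illustrative systems (low / high / intermediate
    diffusion with strands / intermediate diffusion without strands); the
    family entries (ST, BM, S1, S5, S7) carry representative defaults of
    the strand-free, strand-rich and limit-case scenario families.
    """
    nm = dict(n_mito=100, k_out=0.086)
    return {
        # illustrative systems
        "NM9": SimulationParams(D=0.009, **nm),
        "NM10": SimulationParams(D=0.85, **nm),
        "NM11": SimulationParams(D=0.15, n_cyt=5, d_cyt=0.85, k_on=0.85,
                                 k_off=0.43, k_cyt=0.85, **nm),
        "NM12": SimulationParams(D=0.15, **nm),
        # strand-free family representative
        "ST": SimulationParams(D=0.086, **nm),
        # strand-rich family representative (larger population)
        "BM": SimulationParams(n_mito=198, D=0.52, n_cyt=5, d_cyt=0.85,
                               k_on=0.85, k_off=0.43, k_cyt=0.85, k_out=0.086),
        # limit-case scenarios
        "S1": SimulationParams(D=0.05, n_cyt=5, d_cyt=0.85, k_on=0.85,
                               k_off=0.086, k_cyt=2.0, k_out=0.0,
                               n_mito=100),   # polar clustering: fast strands, no loss
        "S5": SimulationParams(D=0.009, k_out=0.0, n_mito=100),  # near-static
        "S7": SimulationParams(D=2.0, **nm),  # very fast diffusion, dense network
    }


def get_preset(name: str, **overrides) -> SimulationParams:
    cat = preset_catalogue()
    if name not in cat:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(cat)}")
    return replace(cat[name], **overrides) if overrides else cat[name]


#: Prior bounds of the random-parameterization (R) family.
R_FAMILY_PRIORS = {"n_mito": (9, 191), "n_cyt": (0, 13), "D": (0.152, 0.705)}


def draw_random_params(seed: int, **overrides) -> SimulationParams:
    """One draw from the random-parameterization family priors.

    n_mito and n_cyt uniform integers, D uniform, within the stated prior
    bounds; strand kinetics (when strands are drawn) take the standard
    strand-system values; boundary turnover at the common 0.086 1/s.
    """
    rng = np.random.default_rng(seed)
    n_mito = int(rng.integers(R_FAMILY_PRIORS["n_mito"][0],
                              R_FAMILY_PRIORS["n_mito"][1] + 1))
    n_cyt = int(rng.integers(R_FAMILY_PRIORS["n_cyt"][0],
                             R_FAMILY_PRIORS["n_cyt"][1] + 1))
    D = float(rng.uniform(*R_FAMILY_PRIORS["D"]))
    base = dict(n_mito=n_mito, n_cyt=n_cyt, D=D, k_out=0.086, seed=seed)
    if n_cyt > 0:
        base.update(d_cyt=0.85, k_on=0.85, k_off=0.43, k_cyt=0.85)
    base.update(overrides)
    return SimulationParams(**base)
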