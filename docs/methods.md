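# Methods

This note records the model, the estimators, the defaults and the design
choices made where the problem was genuinely open, in enough detail to
re-derive every number the package produces.

## Trajectory data model

Trajectories are stored long-format (`track_id, frame, time_s, x_um,
y_um`) inside a `TrackSet` carrying the frame interval, the bounding
region and a provenance label. Coordinates are always micrometres; pixel
data must be converted explicitly (`apply_pixel_scale`), because the
colocalization threshold (1.6 µm) and boundary-region width (4 µm) are
metric. The frame interval is required metadata with default 1.0 s — the
capture interval of simulated data — and **all** time-based statistics use
`time_s`, never frame counts. Within a track, frame indices must strictly
increase and internal gaps may not exceed `max_gap` (default 2 skipped
frames, matching common gap-closing tracker settings); points may exceed a
declared region by at most 0.5 µm, absorbing tracker jitter at crop edges.
Track identity is the tracker's or simulator's: an organelle that leaves
and re-enters the observed region is a *new* node throughout.

TrackMate input is parsed in both dialects (full model XML with
`AllSpots`/`AllTracks`, where trajectories are reassembled from each
track's edge list and never-referenced spots are dropped with a logged
count; and the simplified `<Tracks>/<particle>` export). Spot detection
and linking are upstream concerns: the parser applies no quality
filtering.

## Physical statistics

* **Speed** — Euclidean displacement over *elapsed time* per consecutive
  point pair; across a tracker gap the denominator is the true elapsed
  time, because speed is a rate.
* **Turning angle** — for a frame triplet p₁, p₂, p₃:
  `180 − (180/π)·arccos(a·b/|a||b|)` with a = p₁ − p₂, b = p₃ − p₂, i.e.
  180° minus the interior angle at the middle point. This is equal to the
  turning angle between the two step vectors: 0° for constant direction,
  90° for a right-angle turn, 180° for a reversal. Triplets containing a
  zero-length step are skipped (undefined cosine) and counted.
* **Convex hull** — `scipy.spatial.ConvexHull` area per trajectory of ≥ 3
  points; Qhull's degenerate-geometry failure (collinear or coincident
  points) is mapped to area 0. *MeanCH* is the mean over eligible
  trajectories.
* **Nearest-neighbour distance** — per frame, per organelle, the minimum
  distance to any other organelle in that frame; a lone organelle yields
  NaN and is excluded from means. *InterMitoMean* is the mean over all
  organelle–frames, its CV the population standard deviation over the mean.
* **Diffusion estimate** — time-averaged MSD per lag, averaged over
  tracks, then an ordinary least-squares fit of MSD against lag over lags
  up to `max_lag_s` (default 10 s); D = slope/4 in 2D. The intercept is
  left free because localisation noise offsets MSD; only gap-free tracks
  enter, so lags are uniform. The manual selection of
  "diffusively moving" organelles is the caller's: a helper flags tracks
  whose log–log MSD slope is below 1.2 as diffusive candidates, and by
  default all eligible tracks contribute.
* **Association time** — per unordered pair, the number of frames in
  which the pair is within the colocalization threshold times the frame
  interval. Separate episodes of the same pair are *summed* by default
  ("total"); the longest single episode is also available, since the
  verbal definition admits both readings. Pairs never colocalized are
  absent rather than zero-valued samples.

## Encounter networks

Colocalization is centroid-to-centroid distance ≤ τ, inclusive, default
τ = 1.6 µm; detection is an exhaustive all-pairs check per frame. The
series keeps, per frame, the cumulative node set (every track observed so
far), the cumulative edge set (first-contact frames) and the per-frame
colocalization indicators needed for association times. Singletons are
retained everywhere.

Statistics at a frame (default: final frame): degree distribution, mean
and CV over all nodes; connected components (count, sizes, largest
fraction); global efficiency per the reciprocal-shortest-path formula with
disconnected pairs contributing zero; weighted efficiency with edge
lengths 1/association-time and Dijkstra path lengths — chosen so that unit
association times reproduce the unweighted value exactly; percolation
threshold, the earliest frame whose largest component is ≥ 1.5× (inclusive)
the previous frame's; degree drop, the mean over 200 five-step uniform
random walks from a maximum-degree node (ties broken uniformly per walk,
revisits allowed) of deg(start) − deg(end), normalised by node count; and
average connected neighbours, the mean over nodes of (component size − 1).
Every stochastic statistic takes an explicit seed/generator; defaults are
fixed.

One consequence of the growing node universe worth knowing: *mean* degree
within expanding observation windows can dip slightly for systems with
boundary turnover, because fresh singleton nodes dilute the mean even
though edge counts and per-node degrees only ever increase. Monotonicity
holds strictly at the edge/node level and holds for mean degree whenever
the track population is fixed.

## The agent-based model

One step of length `dt` applies, in order: (1) strand detachment then
attachment, with per-step probabilities `1 − exp(−k·dt)` from the
per-second hazards, attachment requiring distance ≤ `d_cyt` to a strand
(the nearest is taken; travel direction ±1 chosen uniformly); (2) motion —
unattached agents take Gaussian displacements of per-axis variance
`2·D·dt`, attached agents move `k_cyt·dt` parallel to their strand from
their current position (attachment does not snap the agent onto the
strand); (3) contact scaling — agents within `d_mito` of another agent
have the step displacement multiplied by `k_mito`; (4) hydrodynamic
coupling — each agent's displacement gains
`F_hydro · dt · mean_j(v_j / r_ij)` over the other agents' previous
velocities, with `r` floored at 0.1 µm to avoid singularities (the term is
an intentionally crude stand-in for cytoplasmic streaming, not a fluid
solution); (5) boundary truncation — positions are clipped per axis to the
cell rectangle; (6) strand switching — an attached agent passing within
`d_cyt` of an intersection of its strand switches to the crossing strand
with probability 0.5 (configurable; the switching mechanism is part of
the model, the probability is a free choice); (7) boundary turnover — agents within
`d_edge` (default 4 µm) of an edge vanish with the `k_out` per-step
probability and are replaced by a fresh, unattached, zero-velocity agent
with a new identity at a uniform point of the boundary region.

The rule ordering, the post-motion placement of the disappearance check
and per-axis clipping are implementation decisions; no ordering is
prescribed by the model description. `dt` defaults to 1 s — all stated
rates are per-second and the standard capture horizon is 230 s — with
`burn_in` = 1000 discarded steps before `n_frames` = 230 captured frames.
On-strand motion uses `k_cyt` as an absolute speed in µm/s (its units),
not as a velocity scale factor. `d_mito` defaults to 1.6 µm
(the characteristic organelle length) with `k_mito` = 1, so the contact
rule is inert unless enabled.

Presets: NM9 (D = 0.009 µm²/s, k_out = 0.086 s⁻¹), NM10 (D = 0.85),
NM11 (D = 0.15 plus 5 strands, d_cyt = 0.85 µm, k_on = 0.85 s⁻¹,
k_off = 0.43 s⁻¹, k_cyt = 0.85 µm/s), NM12 (D = 0.15, no strands), all
with 100 agents; family representatives ST (strand-free, D = 0.086), BM
(198 agents, strands, D = 0.52; the strand count reuses the standard
value of 5 with the standard strand kinetics), and limit scenarios S1 (fast strands, no boundary loss → polar
clustering), S5 (near-static) and S7 (very fast diffusion). Random
parameter vectors are drawn uniformly within the stated priors (9–191
agents, 0–13 strands, D 0.152–0.705 µm²/s).

## The sweep and windowed analyses

The default tradeoff sweep holds 12 parameterizations: the nine named
presets plus three fixed vectors chosen once as representative draws
within the random-family priors (20/150/60 agents with 3/0/8 strands and
D 0.30/0.20/0.60 µm²/s), spanning sparse-slow through dense-fast
populations. Each run is summarized (network statistics at the final
frame) and rank correlations are computed across runs. Windowed analysis
truncates a TrackSet to frames within `[t0, t0 + w]` and rebuilds the
network from scratch per window; windows are anchored at capture start.

## Synthetic fixtures

Deterministic fixtures (line, reversal, square circuit, static lattice)
have closed-form statistics used as exact oracles. Brownian fixtures are
Gaussian walks of exactly per-axis variance `2·D·dt`, *reflected* at the
region boundary — reflection keeps the sampled diffusion unbiased, unlike
the simulator's truncation rule, which is part of the model proper. The
mixed population draws per-track speeds log-uniformly over an
order-of-magnitude range (default 0.05–1.0 µm/s) and mixes straight-line
movers with Poisson turn events (turn probability 0.1 per frame) and
isotropic diffusers of matching mean step length, optionally with boundary
entry/exit creating fresh identities. These fixtures emulate the
statistical structure of experimental tracks — heterogeneous speeds, mixed
motion modes, right-skewed hull areas, boundary flux — but not tracker
artefacts (localisation noise, missed detections, identity switches), so
tests passing on them demonstrate correctness of the statistics, not
robustness to tracking error.

## Problem sizes and tolerances

Stochastic checks run at the standard study scale (100 agents, 230 frames,
1000-step burn-in) with small seed counts: 5 seeds for the degree-CV
statistic, 10 paired seeds for the strand-effect comparison, 10 seeds for
diffusion recovery (median relative error below 20%), a single seed for
the 12-point sweep correlations. Shorter captures (40–120 frames, reduced
burn-in) are used only in unit tests that check plumbing rather than
distributions. Step-variance validation uses ≥ 10⁵ agent-steps against
`2·D·dt` at 5% relative tolerance; boundary truncation biases this
slightly low, which the large-cell geometry keeps well inside the
tolerance. Exact statistics (angles, closed-form efficiencies, hull areas)
are asserted to machine precision against hand or independent-library
oracles (a dense Floyd–Warshall oracle for shortest paths, an independent
computational-geometry library for hulls).

## Known limitations

The model is 2D and ignores explicit fusion/fission, ATP feedback and real
hydrodynamics. Colocalization is a proximity statement, not a verified
fusion event. Association-time weighting assumes exchange scales with
contact duration. Experimental headline values (e.g. per-cell
nearest-neighbour means) depend on manually curated tracking of the
original videos and are not reproduced here; the package reproduces the
*relationships* — strand transport raising connectivity, the
spread-vs-connectivity tradeoff, window dependence of social but not
physical statistics — on simulated and controlled data.
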