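# mitonet

Encounter-network analysis and agent-based simulation of fragmented
mitochondrial dynamics in plant cells.

Plant mitochondria are not a fused reticulum but hundreds of discrete,
highly motile organelles (the *chondriome*). They must satisfy two
competing demands: spreading evenly through the cell to deliver ATP where
it is needed, and physically meeting one another to exchange genetic
material and protein machinery. `mitonet` quantifies this tension. It
represents colocalization events between tracked organelles as a growing
"social" network, computes physical and network summary statistics from
trajectory data, and contains an agent-based model whose mechanisms
(diffusion, cytoskeletal strand transport, boundary turnover, contact
slowdown, streaming-like coupling) generate the range of behaviours against
which cell data can be compared.

## The core objects

**Encounter network.** Organelles are nodes; an edge joins two organelles
whose centroids have been within τ = 1.6 µm (the characteristic length of a
mitochondrion) in the same frame at any point up to the current one.
Networks are *historical*: edges accumulate and are never removed.
Organelles that never colocalize remain as singleton nodes and are included
in every connectivity statistic.

**Network efficiency.** For a graph *G* with *n* nodes,

```
E(G) = 1/(n(n−1)) · Σ_{i≠j} 1/d(i,j)
```

where *d(i,j)* is the shortest-path length in edges and disconnected pairs
contribute 0. E = 1 for a complete graph; high efficiency means short
social paths, i.e. fast potential sharing of content through the
population. A weighted variant sets each edge's length to the reciprocal of
the pair's association time.

**Physical statistics.** Per-step speed (µm/s); turning angle over frame
triplets, `180 − (180/π)·arccos(a·b/|a||b|)` with **a**, **b** the rays
from the middle point, so 0° is constant direction and 180° a reversal;
convex-hull area swept by each trajectory of ≥ 3 frames (*MeanCH*);
nearest-neighbour distance per organelle per frame (*InterMitoMean*); and a
diffusion coefficient estimated from the slope of the mean-squared
displacement, D = slope/4.

**Agent-based model.** `n_mito` agents in a 30 × 100 µm cell diffuse with
coefficient `D`, attach to / detach from `n_cyt` random linear cytoskeletal
strands at rates `k_on`/`k_off` (moving at `k_cyt` µm/s while attached),
slow by factor `k_mito` on contact, feel an optional inverse-distance
streaming coupling `F_hydro`, and — within 4 µm of the cell edge — vanish
at rate `k_out` to be replaced by a fresh agent (a new track identity), so
the population size is constant. Named presets cover the illustrative
systems NM9–NM12 and the family defaults; random parameter vectors can be
drawn from the stated priors.

## Worked example

```python
from dataclasses import replace
from mitonet import get_preset, run_simulation, summarize

nm11 = summarize(run_simulation(replace(get_preset("NM11"), seed=1)), rng=1)
nm12 = summarize(run_simulation(replace(get_preset("NM12"), seed=1)), rng=1)
print(f"strands:   degree {nm11.mean_degree:.2f}, "
      f"efficiency {nm11.efficiency_unweighted:.3f}")
print(f"diffusion: degree {nm12.mean_degree:.2f}, "
      f"efficiency {nm12.efficiency_unweighted:.3f}")
```

prints

```
strands:   degree 2.09, efficiency 0.034
diffusion: degree 1.43, efficiency 0.012
```

NM11 and NM12 share the same diffusion coefficient (0.15 µm²/s, the
largest experimentally plausible value) and boundary turnover; NM11 adds
five cytoskeletal strands. Strand transport raises the mean number of
encounter partners per organelle from 1.4 to 2.1 and almost triples network
efficiency — active transport buys social connectivity that diffusion at
realistic rates cannot.

The numbered drivers under `analysis/` run the full study sequence:
`01_simulate_presets.py` (trajectories of the four illustrative systems),
`02_summary_statistics.py` (the combined summary table above),
`03_parameter_sweep.py` (a 12-parameterization sweep; Spearman rank
correlation between nearest-neighbour spacing and mean degree comes out
negative, ρ ≈ −0.61, and between hull coverage and degree positive,
ρ ≈ +0.73 — the spread-vs-connectivity tradeoff), and
`04_time_windows.py` (connectivity at 2/39/97/193 s observation windows).
Outputs are written to `results/`.

A thin CLI wraps the same library:

```bash
mitonet simulate --preset NM11 --seed 7 --out tracks.csv
mitonet analyze tracks.csv
mitonet compare-windows tracks.csv --windows 2,39,97,193
mitonet fixtures make --kind lattice --spacing 3 --out lattice.csv
```

Experimental input is accepted as TrackMate XML (model or export dialect)
or as a plain CSV (`track_id,frame,time_s,x_um,y_um`); pixel-unit data
should pass through `apply_pixel_scale` (e.g. 5.0 pixels/µm).

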