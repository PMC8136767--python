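"""Historical encounter networks from organelle trajectories.

Fragmented plant mitochondria interact by transient physical proximity
rather than by fusing into a reticulum, so their "social" structure is
represented as a graph with organelles as nodes and colocalization events
as edges.  Two organelles are colocalized in a frame when their centroids
are at most ``threshold_um`` apart (default 1.6 um, the characteristic
length scale of a mitochondrion).  Networks are *historical*: an edge,
once formed, persists in every later frame, so the per-frame graphs are a
monotonically growing family.  Singletons — organelles observed but never
colocalized — stay in the node set and enter every connectivity statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .trajectory_io import TrackSet

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_UM = 1.6


def detect_colocalizations(positions, threshold_um: float = DEFAULT_THRESHOLD_UM):
    """All unordered pairs of organelles within ``threshold_um`` of each other.

    ``positions`` is either a DataFrame with columns ``track_id, x_um, y_um``
    (one frame's worth of organelles) or a pair ``(ids, xy)`` with ``xy`` an
    ``(n, 2)`` array.  The comparison is inclusive ("at most" the threshold),
    computed by an exhaustive all-pairs check.
    """
    if not threshold_um > 0:
        raise ValueError(f"threshold_um must be positive, got {threshold_um}")
    if isinstance(positions, pd.DataFrame):
        ids = list(positions["track_id"])
        xy = positions[["x_um", "y_um"]].to_numpy(float)
    else:
        ids, xy = positions
        ids = list(ids)
        xy = np.asarray(xy, float)
    n = len(ids)
    if n < 2:
        return []
    d = pdist(xy)  # condensed order matches np.triu_indices(n, k=1)
    iu, ju = np.triu_indices(n, k=1)
    close = d <= threshold_um
    return [frozenset((ids[i], ids[j])) for i, j in zip(iu[close], ju[close])]


@dataclass
class EncounterNetworkSeries:
    """Per-frame cumulative colocalization graphs over a video or simulation.

    ``node_first_frame`` maps each organelle to the frame it was first
    observed; ``edge_first_frame`` maps each unordered pair to its first
    contact frame; ``coloc_frames`` retains, per pair, every frame in which
    the pair was actually within threshold (needed for association times).
    """

    frames: np.ndarray
    node_first_frame: dict
    edge_first_frame: dict
    coloc_frames: dict
    threshold_um: float
    frame_interval_s: float

    @property
    def final_frame(self) -> int:
        return int(self.frames[-1])

    def nodes_at(self, frame: int) -> list:
        return [n for n, f in self.node_first_frame.items() if f <= frame]

    def edges_at(self, frame: int) -> list:
        return [tuple(e) for e, f in self.edge_first_frame.items() if f <= frame]

    def graph_at(self, frame: int | None = None) -> nx.Graph:
        """Cumulative graph at ``frame`` (default: final frame), singletons included."""
        if frame is None:
            frame = self.final_frame
        g = nx.Graph()
        g.add_nodes_from(self.nodes_at(frame))
        for e, f0 in self.edge_first_frame.items():
            if f0 <= frame:
                a, b = tuple(e)
                g.add_edge(a, b, first_contact_frame=int(f0))
        return g


def build_encounter_series(tracks: TrackSet,
                           threshold_um: float = DEFAULT_THRESHOLD_UM,
                           ) -> EncounterNetworkSeries:
    """Accumulate historical colocalization networks over all frames.

    Nodes are every track observed up to each frame, edges the union of all
    colocalizations so far.  Raises on an empty TrackSet.
    """
    if len(tracks.data) == 0:
        raise ValueError("cannot build an encounter network from an empty TrackSet")
    frames = tracks.frames
    node_first: dict = {}
    edge_first: dict = {}
    coloc_frames: dict = {}
    for frame, g in tracks.data.groupby("frame", sort=True):
        frame = int(frame)
        for tid in g["track_id"]:
            node_first.setdefault(tid, frame)
        for pair in detect_colocalizations(g, threshold_um):
            edge_first.setdefault(pair, frame)
            coloc_frames.setdefault(pair, []).append(frame)
    coloc_frames = {p: np.asarray(v, dtype=int) for p, v in coloc_frames.items()}
    return EncounterNetworkSeries(
        frames=frames, node_first_frame=node_first, edge_first_frame=edge_first,
        coloc_frames=coloc_frames, threshold_um=threshold_um,
        frame_interval_s=tracks.frame_interval_s)


# ---------------------------------------------------------------------------
# Graph statistics
# ---------------------------------------------------------------------------

def _as_graph(series_or_graph, frame=None) -> nx.Graph:
    if isinstance(series_or_graph, nx.Graph):
        return series_or_graph
    return series_or_graph.graph_at(frame)


def degree_statistics(series, frame: int | None = None):
    """Degree distribution over *all* nodes (singletons included), mean and CV.

    Returns ``(degrees: pd.Series, mean, cv)``; CV is NaN (flagged) when the
    mean degree is zero.
    """
    g = _as_graph(series, frame)
    degrees = pd.Series(dict(g.degree()), dtype=float)
    mean = float(degrees.mean()) if len(degrees) else float("nan")
    if not len(degrees) or mean == 0:
        logger.info("degree_statistics: zero mean degree, CV undefined")
        return degrees, mean, float("nan")
    cv = float(degrees.std(ddof=0) / mean)
    return degrees, mean, cv


def connected_components(series, frame: int | None = None):
    """Component count (singletons are their own components), sizes, LCC fraction.

    Returns ``(count, sizes_descending, largest_fraction)``.
    """
    g = _as_graph(series, frame)
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    n = g.number_of_nodes()
    frac = sizes[0] / n if n else float("nan")
    return len(sizes), sizes, frac


def graph_efficiency(g: nx.Graph) -> float:
    """Global efficiency E(G) = (1/(n(n-1))) * sum_{i!=j} 1/d(i, j).

    d(i, j) is the unweighted shortest-path length; disconnected pairs
    contribute 0 (reciprocal of an infinite distance).  E is 1 exactly for a
    complete graph and 0 for an edgeless one.  Requires n >= 2.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    total = 0.0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        total += sum(1.0 / d for d in dists.values() if d > 0)
    return total / (n * (n - 1))


def network_efficiency(series, frame: int | None = None) -> float:
    """Unweighted global efficiency of the cumulative graph at ``frame``."""
    return graph_efficiency(_as_graph(series, frame))


def weighted_efficiency(series, frame: int | None = None,
                        association: dict | None = None) -> float:
    """Efficiency with edges weighted by reciprocal association time.

    Each edge gets length ``1 / association_time_s``; d(i, j) is the weighted
    shortest path (sum of lengths, Dijkstra) and the same E(G) formula is
    applied, so long associations shorten paths and the value may exceed 1.
    When all association times are 1 s this reduces exactly to the
    unweighted efficiency.
    """
    if association is None:
        association = association_times_from_series(series)
    g = _as_graph(series, frame)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    for a, b in g.edges():
        t = association.get(frozenset((a, b)), 0.0)
        if not t > 0:
            raise ValueError(
                f"edge ({a}, {b}) has non-positive association time {t}")
        g.edges[a, b]["length"] = 1.0 / t
    total = 0.0
    for _, dists in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        total += sum(1.0 / d for d in dists.values() if d > 0)
    return total / (n * (n - 1))


def association_times_from_series(series: EncounterNetworkSeries,
                                  mode: str = "total") -> dict:
    """Seconds each pair spent within the colocalization threshold.

    ``mode='total'`` sums over all colocalization episodes of a pair;
    ``mode='longest'`` takes the single longest contiguous episode.  Pairs
    never colocalized are absent.
    """
    if mode not in ("total", "longest"):
        raise ValueError(f"mode must be 'total' or 'longest', got {mode!r}")
    dt = series.frame_interval_s
    out = {}
    for pair, frames in series.coloc_frames.items():
        if mode == "total":
            out[pair] = len(frames) * dt
        else:
            runs = np.split(frames, np.where(np.diff(frames) > 1)[0] + 1)
            out[pair] = max(len(r) for r in runs) * dt
    return out


def percolation_threshold(series: EncounterNetworkSeries) -> int | None:
    """First frame at which the largest component grows by >= 50%.

    Scans the cumulative graphs in frame order and returns the earliest
    frame t (t >= second frame) with LCC(t) >= 1.5 * LCC(t-1); the
    comparison is inclusive, the first occurrence wins.  Returns None
    (flagged undefined) when no such jump occurs.
    """
    frames = series.frames
    if len(frames) < 2:
        raise ValueError("percolation threshold needs at least 2 frames")
    prev = None
    for frame in frames:
        _, sizes, _ = connected_components(series, int(frame))
        lcc = sizes[0] if sizes else 0
        if prev is not None and prev > 0 and lcc >= 1.5 * prev:
            return int(frame)
        prev = lcc
    return None


def degree_drop(series, frame: int | None = None, n_walks: int = 200,
                walk_length: int = 5, rng=None) -> float:
    """Mean degree loss along short random walks from a maximum-degree node.

    Each walk starts at a maximum-degree node (ties broken uniformly per
    walk), takes ``walk_length`` uniform random neighbour steps (revisits
    allowed), and records deg(start) - deg(end).  The average over
    ``n_walks`` walks is normalised by the node count, measuring how steeply
    connectivity falls away from hubs.
    """
    g = _as_graph(series, frame)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if g.number_of_edges() == 0:
        raise ValueError("degree_drop undefined for an edgeless graph")
    degrees = dict(g.degree())
    max_deg = max(degrees.values())
    starts = [n for n, d in degrees.items() if d == max_deg]
    neighbours = {n: list(g.neighbors(n)) for n in g.nodes()}
    drops = np.empty(n_walks)
    for w in range(n_walks):
        node = starts[rng.integers(len(starts))]
        start = node
        for _ in range(walk_length):
            nbrs = neighbours[node]
            if not nbrs:  # isolated start cannot happen (max_deg >= 1)
                break
            node = nbrs[rng.integers(len(nbrs))]
        drops[w] = degrees[start] - degrees[node]
    return float(drops.mean() / g.number_of_nodes())


def avg_connected_neighbours(series, frame: int | None = None) -> float:
    """Mean number of other nodes each node can reach (its "social circle").

    Per node this is its component size minus one; singletons contribute 0.
    """
    g = _as_graph(series, frame)
    if g.number_of_nodes() == 0:
        return float("nan")
    total = sum(len(c) * (len(c) - 1) for c in nx.connected_components(g))
    return total / g.number_of_nodes()


# ---------------------------------------------------------------------------
# Summary and export
# ---------------------------------------------------------------------------

@dataclass
class NetworkSummary:
    """All graph statistics of one cumulative encounter network."""

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


def summarize_network(series: EncounterNetworkSeries, frame: int | None = None,
                      rng=None) -> NetworkSummary:
    """Compute every NetworkSummary field at ``frame`` (default final frame)."""
    g = series.graph_at(frame)
    _, mean_deg, cv = degree_statistics(g)
    n_comp, _, lcc_frac = connected_components(g)
    eff = graph_efficiency(g) if g.number_of_nodes() >= 2 else float("nan")
    assoc = association_times_from_series(series)
    try:
        eff_w = weighted_efficiency(series, frame, assoc)
    except ValueError:
        eff_w = None
    try:
        perc = percolation_threshold(series)
    except ValueError:
        perc = None
    try:
        drop = degree_drop(series, frame, rng=rng)
    except ValueError:
        drop = None
    return NetworkSummary(
        n_nodes=g.number_of_nodes(), mean_degree=mean_deg, degree_cv=cv,
        n_components=n_comp, largest_component_fraction=lcc_frac,
        efficiency_unweighted=eff, efficiency_weighted=eff_w,
        percolation_threshold_frame=perc, degree_drop=drop,
        avg_connected_neighbours=avg_connected_neighbours(g))


def _attributed_graph(series: EncounterNetworkSeries, frame: int | None) -> nx.Graph:
    g = series.graph_at(frame)
    assoc = association_times_from_series(series)
    for a, b in g.edges():
        g.edges[a, b]["association_time_s"] = assoc[frozenset((a, b))]
    return g


def export_network(series: EncounterNetworkSeries, frame: int | None, path,
                   format: str = "edgelist") -> None:
    """Write the cumulative graph at ``frame`` to disk.

    ``format='edgelist'`` writes two CSVs (``path`` for edges with
    first_contact_frame and association_time_s, ``path`` + '.nodes.csv' for
    the node list so singletons survive the round trip);
    ``format='graphml'`` writes a single GraphML file.
    """
    g = _attributed_graph(series, frame)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edgelist":
        edges = pd.DataFrame(
            [(a, b, d["first_contact_frame"], d["association_time_s"])
             for a, b, d in g.edges(data=True)],
            columns=["node_a", "node_b", "first_contact_frame", "association_time_s"])
        edges.to_csv(path, index=False)
        pd.DataFrame({"node": list(g.nodes())}).to_csv(
            str(path) + ".nodes.csv", index=False)
    else:
        raise ValueError(f"unknown format {format!r}: use 'edgelist' or 'graphml'")


def load_network(path, format: str = "edgelist") -> nx.Graph:
    """Re-import a graph written by :func:`export_network`."""
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edgelist":
        edges = pd.read_csv(path)
        nodes = pd.read_csv(str(path) + ".nodes.csv")
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes["node"])
        for _, r in edges.iterrows():
            g.add_edge(str(r["node_a"]), str(r["node_b"]),
                       first_contact_frame=int(r["first_contact_frame"]),
                       association_time_s=float(r["association_time_s"]))
        return g
    raise ValueError(f"unknown format {format!r}: use 'edgelist' or 'graphml'")
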