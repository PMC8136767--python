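import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components as cs_components
from scipy.sparse.csgraph import floyd_warshall

from mitonet import fixtures as fx
from mitonet.encounter_network import (
    EncounterNetworkSeries,
    avg_connected_neighbours,
    build_encounter_series,
    connected_components,
    degree_drop,
    degree_statistics,
    detect_colocalizations,
    export_network,
    graph_efficiency,
    load_network,
    network_efficiency,
    percolation_threshold,
    summarize_network,
    weighted_efficiency,
)
from mitonet.simulator import SimulationParams, run_simulation
from mitonet.trajectory_io import empty_trackset

from conftest import trackset_from_rows


def series_from_schedule(n_frames, nodes, edge_frames, dt=1.0):
    """Hand-build a series: ``edge_frames`` maps (a, b) -> first contact frame."""
    edge_first = {frozenset(e): f for e, f in edge_frames.items()}
    return EncounterNetworkSeries(
        frames=np.arange(n_frames),
        node_first_frame={n: 0 for n in nodes},
        edge_first_frame=edge_first,
        coloc_frames={e: np.array([f]) for e, f in edge_first.items()},
        threshold_um=1.6, frame_interval_s=dt)


class TestDetectColocalizations:
    def test_within_threshold(self):
        pairs = detect_colocalizations((["a", "b"], [[0, 0], [1.5, 0]]), 1.6)
        assert pairs == [frozenset(("a", "b"))]

    def test_beyond_threshold(self):
        assert detect_colocalizations((["a", "b"], [[0, 0], [1.7, 0]]), 1.6) == []

    def test_exactly_at_threshold_inclusive(self):
        assert len(detect_colocalizations((["a", "b"], [[0, 0], [1.6, 0]]), 1.6)) == 1

    def test_coincident_organelles(self):
        assert len(detect_colocalizations((["a", "b"], [[2, 2], [2, 2]]), 1.6)) == 1

    def test_threshold_nesting_property(self):
        """pairs(tau') is a subset of pairs(tau) whenever tau' < tau."""
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 10, (30, 2))
        ids = list(range(30))
        loose = set(detect_colocalizations((ids, xy), 1.6))
        strict = set(detect_colocalizations((ids, xy), 1.0))
        assert strict <= loose


class TestBuildSeries:
    def test_edge_appears_at_first_contact_and_persists(self):
        rows = []
        for f in range(6):
            rows.append(("a", f, 0.0, 0.0))
            rows.append(("b", f, 1.0 if f >= 3 else 5.0, 0.0))
        series = build_encounter_series(trackset_from_rows(rows), 1.6)
        for f in range(6):
            has_edge = series.graph_at(f).has_edge("a", "b")
            assert has_edge == (f >= 3)

    def test_no_contact_gives_edgeless_growing_networks(self):
        rows = [("a", 0, 0, 0), ("a", 1, 0, 0), ("b", 1, 10, 0), ("b", 2, 10, 0)]
        series = build_encounter_series(trackset_from_rows(rows), 1.6)
        assert series.graph_at(0).number_of_nodes() == 1
        g = series.graph_at(2)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 0

    def test_sequential_contacts_build_path(self):
        # A meets B at frame 1, B meets C at frame 4 -> final path A-B-C
        rows = []
        for f in range(6):
            rows.append(("b", f, 0.0, 0.0))
            rows.append(("a", f, 1.0 if f >= 1 else 5.0, 0.0))
            rows.append(("c", f, -1.0 if f >= 4 else -5.0, 0.0))
        series = build_encounter_series(trackset_from_rows(rows), 1.6)
        g = series.graph_at()
        assert sorted(map(sorted, g.edges())) == [["a", "b"], ["b", "c"]]

    def test_empty_trackset_rejected(self):
        with pytest.raises(ValueError):
            build_encounter_series(empty_trackset(), 1.6)

    def test_historical_monotonicity(self):
        """Edge count and every degree are non-decreasing in frame index."""
        ts = fx.make_mixed_population(n=40, n_frames=60, seed=11)
        series = build_encounter_series(ts, 1.6)
        prev_edges = -1
        prev_deg: dict = {}
        for f in series.frames:
            g = series.graph_at(int(f))
            assert g.number_of_edges() >= prev_edges
            for node, d in g.degree():
                assert d >= prev_deg.get(node, 0)
            prev_edges = g.number_of_edges()
            prev_deg = dict(g.degree())


class TestDegreeStatistics:
    def test_complete_graph_zero_cv(self):
        s = series_from_schedule(1, "abcd", {(a, b): 0 for a in "abcd"
                                             for b in "abcd" if a < b})
        _, mean, cv = degree_statistics(s, 0)
        assert mean == 3.0 and cv == 0.0

    def test_star_graph(self):
        s = series_from_schedule(1, "habcd", {("h", x): 0 for x in "abcd"})
        degrees, mean, _ = degree_statistics(s, 0)
        assert sorted(degrees) == [1, 1, 1, 1, 4]
        assert mean == pytest.approx(1.6)

    def test_singletons_included(self):
        s = series_from_schedule(1, "abcde",
                                 {("a", "b"): 0, ("b", "c"): 0, ("a", "c"): 0})
        degrees, mean, cv = degree_statistics(s, 0)
        assert sorted(degrees) == [0, 0, 2, 2, 2]
        assert mean == pytest.approx(1.2)

    def test_edgeless_cv_flagged(self):
        s = series_from_schedule(1, "ab", {})
        _, mean, cv = degree_statistics(s, 0)
        assert mean == 0.0 and np.isnan(cv)


class TestComponents:
    def test_edgeless_all_singletons(self):
        s = series_from_schedule(1, "abcde", {})
        count, sizes, frac = connected_components(s, 0)
        assert count == 5 and sizes == [1] * 5 and frac == pytest.approx(0.2)

    def test_triangle_plus_dyad(self):
        s = series_from_schedule(1, "abcde",
                                 {("a", "b"): 0, ("b", "c"): 0, ("a", "c"): 0,
                                  ("d", "e"): 0})
        count, sizes, frac = connected_components(s, 0)
        assert (count, sizes) == (2, [3, 2]) and frac == pytest.approx(0.6)

    def test_bridge_merges_components(self):
        s = series_from_schedule(1, "abcde",
                                 {("a", "b"): 0, ("b", "c"): 0, ("a", "c"): 0,
                                  ("d", "e"): 0, ("c", "d"): 0})
        count, sizes, _ = connected_components(s, 0)
        assert (count, sizes) == (1, [5])


class TestEfficiency:
    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_complete_graph_unity(self, n):
        assert graph_efficiency(nx.complete_graph(n)) == pytest.approx(1.0)

    def test_path_of_three(self):
        assert graph_efficiency(nx.path_graph(3)) == pytest.approx(5 / 6)

    def test_two_disjoint_dyads(self):
        g = nx.Graph([(0, 1), (2, 3)])
        assert graph_efficiency(g) == pytest.approx(1 / 3)

    def test_edgeless_zero(self):
        g = nx.empty_graph(4)
        assert graph_efficiency(g) == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            graph_efficiency(nx.empty_graph(1))

    def test_adding_shortcut_strictly_increases(self):
        g = nx.path_graph(5)
        before = graph_efficiency(g)
        g.add_edge(0, 4)
        assert graph_efficiency(g) > before

    def test_matches_floyd_warshall_oracle_on_random_graphs(self):
        """Efficiency and components vs a dense all-pairs oracle, 100 graphs."""
        rng = np.random.default_rng(123)
        for trial in range(100):
            n = int(rng.integers(2, 51))
            p = rng.uniform(0.02, 0.3)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            a = nx.to_scipy_sparse_array(g, format="csr")
            d = floyd_warshall(a, directed=False, unweighted=True)
            mask = ~np.eye(n, dtype=bool)
            finite = np.isfinite(d) & mask
            expected_eff = (1.0 / d[finite]).sum() / (n * (n - 1))
            assert graph_efficiency(g) == pytest.approx(expected_eff)
            n_comp, _ = cs_components(a, directed=False)
            series_count = len(list(nx.connected_components(g)))
            assert series_count == n_comp


class TestWeightedEfficiency:
    def _series_with_assoc(self, assoc_frames):
        rows = []
        for f in range(10):
            rows.append(("a", f, 0.0, 0.0))
            rows.append(("b", f, 1.0 if f < assoc_frames else 9.0, 0.0))
        return build_encounter_series(trackset_from_rows(rows), 1.6)

    def test_dyad_one_second(self):
        assert weighted_efficiency(self._series_with_assoc(1)) == pytest.approx(1.0)

    def test_dyad_two_seconds(self):
        assert weighted_efficiency(self._series_with_assoc(2)) == pytest.approx(2.0)

    def test_disconnected_pairs_contribute_zero(self):
        rows = []
        for f in range(4):
            rows.append(("a", f, 0.0, 0.0))
            rows.append(("b", f, 1.0, 0.0))
            rows.append(("c", f, 20.0, 0.0))
        series = build_encounter_series(trackset_from_rows(rows), 1.6)
        # dyad contributes 2 * (1/(1/4s)) = 8; 4 cross pairs contribute 0
        assert weighted_efficiency(series) == pytest.approx(8 / 6)

    def test_unit_association_reduces_to_unweighted(self):
        s = series_from_schedule(1, "abc", {("a", "b"): 0, ("b", "c"): 0})
        assoc = {e: 1.0 for e in s.edge_first_frame}
        assert weighted_efficiency(s, 0, assoc) == pytest.approx(
            network_efficiency(s, 0))

    def test_zero_association_rejected(self):
        s = series_from_schedule(1, "ab", {("a", "b"): 0})
        with pytest.raises(ValueError):
            weighted_efficiency(s, 0, {frozenset(("a", "b")): 0.0})


class TestPercolation:
    def _series_with_lcc(self, edge_frames):
        return series_from_schedule(5, "abcdef", edge_frames)

    def test_doubling_jump(self):
        # LCC sizes 2,2,4,...: first >=50% growth at frame 2
        s = self._series_with_lcc({("a", "b"): 0, ("c", "d"): 2, ("b", "c"): 2})
        assert percolation_threshold(s) == 2

    def test_exact_fifty_percent_inclusive(self):
        # LCC sizes 2,2,3,...: exactly 1.5x at frame 2 counts
        s = self._series_with_lcc({("a", "b"): 0, ("b", "c"): 2})
        assert percolation_threshold(s) == 2

    def test_constant_lcc_undefined(self):
        s = self._series_with_lcc({("a", "b"): 0})
        assert percolation_threshold(s) is None

    def test_single_frame_rejected(self):
        s = series_from_schedule(1, "ab", {("a", "b"): 0})
        with pytest.raises(ValueError):
            percolation_threshold(s)


class TestDegreeDrop:
    def test_complete_graph_zero(self):
        s = series_from_schedule(1, "abcd", {(a, b): 0 for a in "abcd"
                                             for b in "abcd" if a < b})
        assert degree_drop(s, 0, rng=0) == 0.0

    def test_cycle_zero(self):
        s = series_from_schedule(1, "abcd", {("a", "b"): 0, ("b", "c"): 0,
                                             ("c", "d"): 0, ("d", "a"): 0})
        assert degree_drop(s, 0, rng=0) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_star_parity_exact_regardless_of_rng(self, seed):
        # 5-step walks from the hub always end on a leaf: (4-1)/5 = 0.6
        s = series_from_schedule(1, "habcd", {("h", x): 0 for x in "abcd"})
        assert degree_drop(s, 0, rng=seed) == pytest.approx(0.6)

    def test_edgeless_rejected(self):
        s = series_from_schedule(1, "ab", {})
        with pytest.raises(ValueError):
            degree_drop(s, 0, rng=0)


class TestAvgConnectedNeighbours:
    def test_edgeless_zero(self):
        s = series_from_schedule(1, "abcd", {})
        assert avg_connected_neighbours(s, 0) == 0.0

    def test_single_component(self):
        s = series_from_schedule(1, "abcde", {("a", "b"): 0, ("b", "c"): 0,
                                              ("c", "d"): 0, ("d", "e"): 0})
        assert avg_connected_neighbours(s, 0) == 4.0

    def test_triangle_plus_singletons(self):
        s = series_from_schedule(1, "abcde",
                                 {("a", "b"): 0, ("b", "c"): 0, ("a", "c"): 0})
        assert avg_connected_neighbours(s, 0) == pytest.approx(1.2)


class TestExport:
    def _triangle_series(self):
        rows = []
        for f in range(3):
            for tid, x in (("a", 0.0), ("b", 1.0), ("c", 0.5)):
                rows.append((tid, f, x, 0.0))
            rows.append(("lonely", f, 20.0, 0.0))
        return build_encounter_series(trackset_from_rows(rows), 1.6)

    @pytest.mark.parametrize("fmt", ["edgelist", "graphml"])
    def test_round_trip_preserves_graph_and_attributes(self, tmp_path, fmt):
        series = self._triangle_series()
        suffix = ".graphml" if fmt == "graphml" else ".csv"
        path = tmp_path / f"net{suffix}"
        export_network(series, None, path, format=fmt)
        g = load_network(path, format=fmt)
        orig = series.graph_at()
        assert set(g.nodes()) == set(orig.nodes())
        assert {frozenset(e) for e in g.edges()} == {frozenset(e)
                                                     for e in orig.edges()}
        for a, b in g.edges():
            assert float(g.edges[a, b]["association_time_s"]) == pytest.approx(3.0)
            assert int(g.edges[a, b]["first_contact_frame"]) == 0

    def test_singleton_only_graph(self, tmp_path):
        rows = [(t, 0, x, 0.0) for t, x in (("a", 0.0), ("b", 10.0), ("c", 20.0))]
        series = build_encounter_series(trackset_from_rows(rows), 1.6)
        path = tmp_path / "net.csv"
        export_network(series, None, path, format="edgelist")
        g = load_network(path, format="edgelist")
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(self._triangle_series(), None, tmp_path / "x", "dot")


class TestThresholdRobustness:
    def test_pipeline_runs_at_stricter_threshold_and_ordering_persists(self):
        """NM11 keeps its connectivity edge over NM12 at tau = 1.0 um."""
        from mitonet.pipeline import summarize
        from mitonet.simulator import get_preset
        from dataclasses import replace
        wins = 0
        for seed in range(3):
            small = dict(n_frames=120, burn_in=300)
            t11 = run_simulation(replace(get_preset("NM11"), seed=seed, **small))
            t12 = run_simulation(replace(get_preset("NM12"), seed=seed, **small))
            r11 = summarize(t11, threshold_um=1.0, rng=seed)
            r12 = summarize(t12, threshold_um=1.0, rng=seed)
            wins += r11.mean_degree > r12.mean_degree
        assert wins >= 2


def test_summarize_network_fields_consistent():
    ts = fx.make_mixed_population(n=30, n_frames=40, seed=5)
    series = build_encounter_series(ts, 1.6)
    summ = summarize_network(series, rng=np.random.default_rng(0))
    assert summ.n_nodes == len(series.node_first_frame)
    assert 0.0 <= summ.efficiency_unweighted <= 1.0
    assert 1 <= summ.n_components <= summ.n_nodes
    assert 0.0 < summ.largest_component_fraction <= 1.0
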