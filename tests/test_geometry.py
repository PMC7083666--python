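import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import streammeta as sm
from streammeta.geometry import DistanceTriplet


def make_sites(coords, elevation=0.0):
    n = len(coords)
    return pd.DataFrame({
        "site_id": [f"s{i}" for i in range(n)],
        "x": [c[0] for c in coords],
        "y": [c[1] for c in coords],
        "elevation": elevation,
        "stream_id": "ST1",
        "subbasin_id": "SB1",
    })


class TestGeographic:
    def test_pythagorean_pair(self):
        d = sm.geographic_distance(make_sites([(0, 0), (3, 4)]))
        assert d.iloc[0, 1] == pytest.approx(5.0)
        assert d.iloc[0, 0] == 0.0 and d.iloc[1, 1] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        coords = rng.random((10, 2)) * 100
        d = sm.geographic_distance(make_sites(coords)).to_numpy()
        for i in range(10):
            for j in range(10):
                expect = np.hypot(*(coords[i] - coords[j]))
                assert abs(d[i, j] - expect) < 1e-12

    def test_duplicate_site_id_rejected(self):
        sites = make_sites([(0, 0), (1, 1)])
        sites.loc[1, "site_id"] = "s0"
        with pytest.raises(ValueError, match="duplicate"):
            sm.geographic_distance(sites)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=8, unique=True))
    def test_symmetry_and_triangle_inequality(self, coords):
        d = sm.geographic_distance(make_sites(coords)).to_numpy()
        assert np.allclose(d, d.T)
        n = len(coords)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestTopographic:
    def test_flat_surface_equals_geographic(self):
        sites = make_sites([(0, 0), (3, 4), (7, 1)])
        flat = sm.FunctionSurface(lambda x, y: np.full(np.shape(x), 1.5))
        top = sm.topographic_distance(sites, flat, step=0.1)
        geo = sm.geographic_distance(sites)
        assert np.allclose(top.to_numpy(), geo.to_numpy())

    @pytest.mark.parametrize("step", [0.5, 0.05, 0.013])
    def test_linear_ramp_3_4_5(self, step):
        # 3 km horizontal with a linear 4 km elevation gain: length 5 km
        sites = make_sites([(0, 0), (3, 0)])
        ramp = sm.FunctionSurface(lambda x, y: (4.0 / 3.0) * x)
        top = sm.topographic_distance(sites, ramp, step=step)
        assert top.iloc[0, 1] == pytest.approx(5.0, abs=1e-9)

    def test_sinusoidal_surface_converges_to_fine_step(self):
        sites = make_sites([(0, 0), (2, 1)])
        surf = sm.FunctionSurface(lambda x, y: 0.3 * np.sin(2 * x) + 0.2 * np.cos(3 * y))
        coarse = sm.topographic_distance(sites, surf, step=0.01).iloc[0, 1]
        fine = sm.topographic_distance(sites, surf, step=0.0001).iloc[0, 1]
        assert abs(coarse - fine) / fine < 1e-3

    def test_halving_step_changes_result_little(self):
        sites = make_sites([(0, 0), (5, 3), (1, 4)])
        surf = sm.FunctionSurface(lambda x, y: 0.5 * np.sin(x) * np.cos(y))
        a = sm.topographic_distance(sites, surf, step=0.02).to_numpy()
        b = sm.topographic_distance(sites, surf, step=0.01).to_numpy()
        off = ~np.eye(3, dtype=bool)
        assert np.all(np.abs(a[off] - b[off]) / b[off] < 0.005)

    def test_out_of_domain_flagged_missing(self):
        sites = make_sites([(0, 0), (10, 0)])
        grid = sm.GridSurface(np.linspace(0, 5, 6), np.linspace(-1, 1, 3),
                              np.zeros((6, 3)))
        top = sm.topographic_distance(sites, grid, step=0.5)
        assert np.isnan(top.iloc[0, 1])

    def test_grid_surface_bilinear(self):
        grid = sm.GridSurface(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                              np.array([[0.0, 1.0], [1.0, 2.0]]))
        assert grid(np.array(0.5), np.array(0.5)) == pytest.approx(1.0)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            sm.topographic_distance(make_sites([(0, 0), (1, 0)]),
                                    sm.FunctionSurface(lambda x, y: x), step=0.0)


def chain_network(lengths, coords):
    g = nx.Graph()
    for i, (x, y) in enumerate(coords):
        g.add_node(f"N{i}", x=x, y=y, elevation=0.0)
    for i, ln in enumerate(lengths):
        g.add_edge(f"N{i}", f"N{i + 1}", length=ln)
    return g


class TestWatercourse:
    def test_chain_sum(self):
        g = chain_network([2.0, 3.0], [(0, 0), (1, 0), (2, 0)])
        net = sm.StreamNetwork(graph=g, site_to_node={"s0": "N0", "s1": "N2"})
        sites = make_sites([(0, 0), (2, 0)])
        w = sm.watercourse_distance(sites, net)
        assert w.iloc[0, 1] == pytest.approx(5.0)
        assert w.iloc[0, 0] == 0.0

    def test_matches_tree_path_enumeration(self):
        # random tree on 12 nodes: on a tree the unique path is the shortest
        rng = np.random.default_rng(3)
        g = nx.random_labeled_tree(12, seed=5)
        tree = nx.Graph()
        pos = rng.random((12, 2)) * 10
        for n in g.nodes:
            tree.add_node(n, x=pos[n, 0], y=pos[n, 1], elevation=0.0)
        for u, v in g.edges:
            euclid = np.hypot(*(pos[u] - pos[v]))
            tree.add_edge(u, v, length=euclid * 1.3)
        sites = make_sites(pos)
        net = sm.StreamNetwork(graph=tree,
                               site_to_node={f"s{i}": i for i in range(12)})
        w = sm.watercourse_distance(sites, net).to_numpy()
        for i in range(12):
            for j in range(12):
                path = nx.shortest_path(tree, i, j)
                expect = sum(tree.edges[a, b]["length"]
                             for a, b in zip(path, path[1:]))
                assert abs(w[i, j] - expect) < 1e-9

    def test_disconnected_pairs_missing(self):
        g = chain_network([1.0], [(0, 0), (1, 0)])
        g.add_node("N9", x=5.0, y=5.0, elevation=0.0)
        net = sm.StreamNetwork(graph=g, site_to_node={"s0": "N0", "s1": "N9"})
        sites = make_sites([(0, 0), (5, 5)])
        w = sm.watercourse_distance(sites, net)
        assert np.isnan(w.iloc[0, 1]) and w.iloc[0, 0] == 0.0

    def test_unmapped_site_rejected(self):
        g = chain_network([1.0], [(0, 0), (1, 0)])
        net = sm.StreamNetwork(graph=g, site_to_node={"s0": "N0"})
        with pytest.raises(ValueError, match="s1"):
            sm.watercourse_distance(make_sites([(0, 0), (1, 0)]), net)

    def test_snap_tolerance_enforced(self):
        nodes = pd.DataFrame({"node_id": ["N0", "N1"], "x": [0.0, 1.0],
                              "y": [0.0, 0.0], "elevation": [0.0, 0.0]})
        edges = pd.DataFrame({"node_a": ["N0"], "node_b": ["N1"], "length": [1.0]})
        far = make_sites([(0, 0), (1, 0.5)])
        with pytest.raises(ValueError, match="snap tolerance"):
            sm.StreamNetwork.from_frames(nodes, edges, far, snap_tolerance=0.1)

    def test_edge_shorter_than_euclid_rejected(self):
        nodes = pd.DataFrame({"node_id": ["N0", "N1"], "x": [0.0, 3.0],
                              "y": [0.0, 4.0], "elevation": [0.0, 0.0]})
        edges = pd.DataFrame({"node_a": ["N0"], "node_b": ["N1"], "length": [2.0]})
        with pytest.raises(ValueError, match="shorter"):
            sm.StreamNetwork.from_frames(nodes, edges)


class TestSummaries:
    def test_single_pair(self):
        sites = make_sites([(0, 0), (5, 0)])
        geo = sm.geographic_distance(sites)
        trip = DistanceTriplet(geo=geo, top=geo.copy(), wat=geo.copy())
        s = sm.summarize_distances(trip).loc["GEO"]
        assert (s["mean"], s["min"], s["max"], s["sd"]) == (5.0, 5.0, 5.0, 0.0)

    def test_three_pair_hand_calculation(self):
        # pair distances {1, 2, 3}: mean 2, sample sd 1
        sites = make_sites([(0, 0), (1, 0), (3, 0)])
        geo = sm.geographic_distance(sites)
        trip = DistanceTriplet(geo=geo, top=geo.copy(), wat=geo.copy())
        s = sm.summarize_distances(trip).loc["GEO"]
        assert s["mean"] == pytest.approx(2.0)
        assert s["sd"] == pytest.approx(1.0)  # ddof=1 over {1,2,3}

    def test_missing_counted_and_all_missing_rejected(self):
        sites = make_sites([(0, 0), (1, 0), (3, 0)])
        geo = sm.geographic_distance(sites)
        wat = geo.copy()
        wat.iloc[0, 2] = wat.iloc[2, 0] = np.nan
        trip = DistanceTriplet(geo=geo, top=geo.copy(), wat=wat)
        assert sm.summarize_distances(trip).loc["WAT", "n_missing"] == 1
        allnan = geo.copy()
        allnan.values[~np.eye(3, dtype=bool)] = np.nan
        with pytest.raises(ValueError, match="missing"):
            sm.summarize_distances(DistanceTriplet(geo=geo, top=geo.copy(), wat=allnan))

    def test_triplet_ordering_enforced(self):
        sites = make_sites([(0, 0), (1, 0)])
        geo = sm.geographic_distance(sites)
        short = geo * 0.5
        with pytest.raises(ValueError, match=">= GEO"):
            DistanceTriplet(geo=geo, top=short, wat=geo.copy())


class TestGeneratedDesignContracts:
    def test_top_and_wat_dominate_geo(self, small_triplet):
        geo = small_triplet["GEO"].to_numpy()
        for route in ("TOP", "WAT"):
            other = small_triplet[route].to_numpy()
            assert np.all(other >= geo - 1e-9)

    def test_wat_triangle_inequality(self, small_triplet):
        w = small_triplet["WAT"].to_numpy()
        n = w.shape[0]
        for i in range(0, n, 3):
            for j in range(n):
                for k in range(n):
                    assert w[i, j] <= w[i, k] + w[k, j] + 1e-9
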