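"""Centrality measures against brute-force oracles, and the M statistics."""

import itertools

import numpy as np
import pytest

from lactonet import (
    FunctionalNetwork,
    NetworkGenConfig,
    StructuralNetwork,
    centralities,
    centrality_density,
    centrality_difference,
    compare_to_baseline,
    degree_density_correlation,
    make_center_satellite,
    make_multi_arm,
    powerlaw_configuration,
    remove_edge,
)


# -- brute-force oracles (independent of networkx's algorithms) --------

def bfs_distances(net, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in net.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def closeness_oracle(net):
    """Component-corrected normalized (Wasserman-Faust) closeness."""
    n = net.n_nodes
    out = np.zeros(n)
    for u in range(n):
        dist = bfs_distances(net, u)
        reachable = len(dist) - 1
        total = sum(dist.values())
        if reachable > 0:
            out[u] = (reachable / total) * (reachable / (n - 1))
    return out


def betweenness_oracle(net):
    """Enumerate every shortest path between every pair (small graphs)."""
    n = net.n_nodes
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = list(all_shortest_paths(net, s, t))
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            out[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return out / norm if norm > 0 else out


def all_shortest_paths(net, s, t):
    dist = bfs_distances(net, s)
    if t not in dist:
        return
    stack = [[s]]
    while stack:
        path = stack.pop()
        u = path[-1]
        if u == t:
            yield path
            continue
        for v in net.neighbors(u):
            if dist.get(v, -1) == dist[u] + 1 and dist[v] <= dist[t]:
                stack.append(path + [v])


def eigenvector_oracle(net):
    """Dense eigendecomposition per component, global max scaled to 1."""
    import networkx as nx

    g = net.to_networkx()
    out = np.zeros(net.n_nodes)
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            continue
        a = nx.to_numpy_array(g, nodelist=nodes)
        w, v = np.linalg.eigh(a)
        vec = np.abs(v[:, np.argmax(w)])
        out[nodes] = vec
    m = out.max()
    return out / m if m > 0 else out


SMALL_GRAPHS = {
    "path3": StructuralNetwork(3, [(0, 1), (1, 2)]),
    "star5": make_center_satellite(5),
    "multiarm": make_multi_arm(),
    "multiarm_cut": remove_edge(make_multi_arm(), 2, 7),
    "powerlaw20": powerlaw_configuration(NetworkGenConfig(n=20, gamma=2.8, seed=3)),
    "cycle6": StructuralNetwork(6, [(i, (i + 1) % 6) for i in range(6)]),
}


class TestCentralities:
    def test_path_graph_known_values(self):
        rep = centralities(SMALL_GRAPHS["path3"])
        assert rep.closeness == pytest.approx([2 / 3, 1.0, 2 / 3])
        assert rep.betweenness == pytest.approx([0.0, 1.0, 0.0])
        assert rep.degree.tolist() == [1, 2, 1]

    def test_star_center_closeness_is_one(self):
        rep = centralities(SMALL_GRAPHS["star5"])
        assert rep.closeness[0] == pytest.approx(1.0)
        assert rep.eigenvector[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("name", sorted(SMALL_GRAPHS))
    def test_matches_brute_force_oracles(self, name):
        net = SMALL_GRAPHS[name]
        rep = centralities(net)
        assert rep.closeness == pytest.approx(closeness_oracle(net), abs=1e-10)
        assert rep.betweenness == pytest.approx(betweenness_oracle(net), abs=1e-10)
        assert rep.eigenvector == pytest.approx(eigenvector_oracle(net), abs=1e-7)

    def test_multiarm_rings_equal_and_decreasing(self, multiarm):
        """Automorphic ring nodes get equal values, declining outwards."""
        rep = centralities(multiarm)
        for metric in ("degree", "closeness", "betweenness", "eigenvector"):
            vals = rep.values(metric)
            ring_vals = []
            for ring in multiarm.rings:
                nodes = sorted(ring)
                assert np.ptp(vals[nodes]) < 1e-9, metric
                ring_vals.append(vals[nodes[0]])
            if metric != "degree":  # degree ties between rings 1 and 2
                assert vals[0] > ring_vals[0] > ring_vals[1] > ring_vals[2]

    def test_star_satellites_equal(self):
        rep = centralities(SMALL_GRAPHS["star5"])
        for metric in ("closeness", "betweenness", "eigenvector"):
            assert np.ptp(rep.values(metric)[1:]) < 1e-9

    def test_closeness_changes_from_edge_edits(self, multiarm):
        """Edge edits move closeness at (at least) the nodes the study names."""
        from lactonet import add_edge

        base = centralities(multiarm).closeness

        def changed(net2):
            return set(np.flatnonzero(
                ~np.isclose(centralities(net2).closeness, base)))

        assert {2, 7, 12} <= changed(remove_edge(multiarm, 2, 7))
        assert {5, 7, 10} <= changed(add_edge(multiarm, 5, 7))
        assert {2, 5, 7, 10} <= changed(add_edge(multiarm, 7, 10))


class TestCentralityDifference:
    def test_equal_values_give_zero(self):
        f = FunctionalNetwork.from_edges(4, [(0, 1), (2, 3)], 0.99)
        assert centrality_difference(f, np.full(4, 0.7)) == 0.0

    def test_single_edge(self):
        f = FunctionalNetwork.from_edges(2, [(0, 1)], 0.99)
        assert centrality_difference(f, np.array([0.5, 0.3])) == pytest.approx(0.2)

    def test_empty_rejected(self):
        f = FunctionalNetwork.from_edges(4, [], 0.99)
        with pytest.raises(ValueError):
            centrality_difference(f, np.zeros(4))

    def test_bounded_and_label_invariant(self, rng):
        values = rng.random(10)
        edges = [(0, 3), (1, 2), (4, 9), (5, 6)]
        f = FunctionalNetwork.from_edges(10, edges, 0.99)
        m = centrality_difference(f, values)
        assert m <= np.ptp(values) + 1e-12
        perm = rng.permutation(10)
        pedges = [(perm[i], perm[j]) for i, j in edges]
        fp = FunctionalNetwork.from_edges(10, pedges, 0.99)
        assert centrality_difference(fp, values[np.argsort(perm)]) == pytest.approx(m)


class TestCompareToBaseline:
    def make_functionals(self, rng, n=12, count=8):
        nets = []
        for _ in range(count):
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.2]
            if not edges:
                edges = [(0, 1)]
            nets.append(FunctionalNetwork.from_edges(n, edges, 0.99))
        return nets

    def test_identity_baseline_is_degenerate(self, rng):
        nets = self.make_functionals(rng)
        values = rng.random(12)
        cmp_ = compare_to_baseline(nets, values, seed=0,
                                   baseline_factory=lambda f: f)
        assert cmp_.degenerate
        assert cmp_.pvalue == 1.0
        assert cmp_.median_functional == cmp_.median_baseline

    def test_paired_lengths_and_determinism(self, rng):
        nets = self.make_functionals(rng)
        values = rng.random(12)
        a = compare_to_baseline(nets, values, seed=5)
        b = compare_to_baseline(nets, values, seed=5)
        assert len(a.m_functional) == len(a.m_baseline) == len(nets)
        assert np.array_equal(a.m_functional, b.m_functional)
        assert np.array_equal(a.m_baseline, b.m_baseline)
        assert 0.0 <= a.pvalue <= 1.0

    def test_edgeless_networks_skipped(self, rng):
        nets = self.make_functionals(rng, count=4)
        nets.append(FunctionalNetwork.from_edges(12, [], 0.99))
        cmp_ = compare_to_baseline(nets, rng.random(12), seed=1)
        assert cmp_.n_skipped == 1
        assert len(cmp_.m_functional) == 4


class TestCentralityDensity:
    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning):
            d = centrality_density(np.full(5, 0.3))
        assert np.ptp(d) == 0.0

    def test_modes_denser_than_valley(self):
        values = np.concatenate([np.random.default_rng(0).normal(0, 0.05, 50),
                                 np.random.default_rng(1).normal(1, 0.05, 50),
                                 [0.5]])
        d = centrality_density(values)
        assert d[:50].mean() > d[-1]
        assert d[50:100].mean() > d[-1]

    def test_kde_integrates_to_one(self, rng):
        from scipy import stats

        values = rng.normal(size=40)
        kde = stats.gaussian_kde(values, bw_method="silverman")
        xs = np.linspace(values.min() - 5, values.max() + 5, 4001)
        integral = np.trapezoid(kde(xs), xs)
        assert integral == pytest.approx(1.0, abs=1e-3)
        # densities() returns this KDE evaluated at the sample itself
        assert centrality_density(values) == pytest.approx(kde(values))


class TestDegreeDensityCorrelation:
    def test_perfectly_linear(self):
        x = np.arange(10.0)
        r, p = degree_density_correlation(x, 2.0 * x + 1.0)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            degree_density_correlation(np.ones(5), np.arange(5.0))

    def test_null_rarely_exceeds_half(self):
        """Independent samples (n=100) give |r| < 0.5 almost always."""
        rng = np.random.default_rng(7)
        exceed = 0
        for _ in range(1000):
            r, _ = degree_density_correlation(rng.normal(size=100),
                                              rng.normal(size=100))
            exceed += abs(r) >= 0.5
        assert exceed <= 50  # >= 95% stay below 0.5

    def test_spearman_option(self):
        x = np.arange(10.0)
        r, _ = degree_density_correlation(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)
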