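"""Structural (gap-junction) network construction and IO.

A structural network is an undirected simple graph whose nodes are cells
and whose edges are bidirectional electrical couplings.  Generators cover
the topologies used throughout the study: a coupled pair, center/satellite
stars, multi-arm trees, and scale-free configuration-model graphs, plus an
Erdos-Renyi edge-rewiring baseline for functional networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "StructuralNetwork",
    "NetworkGenConfig",
    "make_pair",
    "make_center_satellite",
    "make_multi_arm",
    "add_edge",
    "remove_edge",
    "powerlaw_configuration",
    "erdos_renyi_baseline",
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
]


class StructuralNetwork:
    """Undirected simple graph of electrically coupled cells.

    Nodes are the integers ``0 .. n-1``.  The graph is immutable from the
    outside; :func:`add_edge` / :func:`remove_edge` return new networks.
    """

    def __init__(self, n_nodes: int, edges, labels: dict[int, str] | None = None):
        if n_nodes < 1:
            raise ValueError("network needs at least one node")
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(f"edge ({i},{j}) outside node range")
            g.add_edge(i, j)
        self._graph = g
        self.labels = dict(labels) if labels else {}

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self._graph.edges())

    def neighbors(self, i: int) -> set[int]:
        """Neighbor set N_i of cell ``i``."""
        return set(self._graph.neighbors(i))

    def degrees(self) -> np.ndarray:
        return np.array([self._graph.degree(i) for i in range(self.n_nodes)])

    def has_edge(self, i: int, j: int) -> bool:
        return self._graph.has_edge(i, j)

    def to_networkx(self) -> nx.Graph:
        return self._graph.copy()

    def adjacency_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self._graph, nodelist=range(self.n_nodes))

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two int64 arrays (sorted edge order)."""
        e = self.edges()
        if not e:
            return (np.empty(0, dtype=np.int64),) * 2
        arr = np.asarray(e, dtype=np.int64)
        return np.ascontiguousarray(arr[:, 0]), np.ascontiguousarray(arr[:, 1])

    def laplacian_matrix(self) -> np.ndarray:
        """Dense graph Laplacian D - A; the coupling current is g_c * (L @ V)."""
        a = self.adjacency_matrix()
        return np.diag(a.sum(axis=1)) - a

    def __eq__(self, other) -> bool:
        if not isinstance(other, StructuralNetwork):
            return NotImplemented
        return self.n_nodes == other.n_nodes and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"StructuralNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class NetworkGenConfig:
    """Configuration of the power-law configuration-model generator."""

    n: int = 100            # node count
    gamma: float = 2.8      # power-law exponent of p(k) ~ k^-gamma
    # k_min = 2 keeps the realized graph a single connected blob with a
    # dominant hub (k_min = 1 at this exponent yields a subcritical
    # forest of ~30 fragments instead of one scale-free network)
    k_min: int = 2          # smallest allowed degree
    k_max: int | None = None  # largest allowed degree (default n - 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_max is None:
            self.k_max = self.n - 1
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        if not (1 <= self.k_min <= self.k_max < self.n):
            raise ValueError("need 1 <= k_min <= k_max < n")


def make_pair() -> StructuralNetwork:
    """Two bidirectionally coupled cells."""
    return StructuralNetwork(2, [(0, 1)])


def make_center_satellite(m: int) -> StructuralNetwork:
    """Star network: one center cell coupled to ``m`` satellite cells.

    Node 0 is the center; satellites are 1..m and are not coupled to each
    other.  The degree of the center equals the satellite count.
    """
    if m < 1:
        raise ValueError("need at least one satellite")
    labels = {0: "center"}
    labels.update({i: f"S{i}" for i in range(1, m + 1)})
    return StructuralNetwork(m + 1, [(0, i) for i in range(1, m + 1)], labels)


def make_multi_arm(arms: int = 5, arm_length: int = 3) -> StructuralNetwork:
    """Center cell with ``arms`` chains of ``arm_length`` cells radiating out.

    Node numbering places ring ``r`` (distance r from the center) at nodes
    ``(r-1)*arms + 1 .. r*arms``, so arm ``a`` is the path
    ``0 - a - (a+arms) - (a+2*arms) - ...``.  With the defaults (5 arms of
    3) this gives 16 nodes and 15 edges, rings {1..5}, {6..10}, {11..15}.
    """
    if arms < 1 or arm_length < 1:
        raise ValueError("arms and arm_length must be >= 1")
    edges = []
    for a in range(1, arms + 1):
        edges.append((0, a))
        for r in range(1, arm_length):
            edges.append(((r - 1) * arms + a, r * arms + a))
    labels = {0: "center"}
    net = StructuralNetwork(1 + arms * arm_length, edges, labels)
    net.rings = [  # type: ignore[attr-defined]
        frozenset(range((r - 1) * arms + 1, r * arms + 1))
        for r in range(1, arm_length + 1)
    ]
    return net


def _copy_with_edges(net: StructuralNetwork, edges) -> StructuralNetwork:
    out = StructuralNetwork(net.n_nodes, edges, net.labels)
    if hasattr(net, "rings"):
        out.rings = net.rings  # type: ignore[attr-defined]
    return out


def add_edge(net: StructuralNetwork, i: int, j: int) -> StructuralNetwork:
    """Return a copy of ``net`` with the absent edge (i, j) added."""
    if i == j:
        raise ValueError("self-loops are not allowed")
    if not (0 <= i < net.n_nodes and 0 <= j < net.n_nodes):
        raise ValueError(f"node out of range: ({i},{j})")
    if net.has_edge(i, j):
        raise ValueError(f"edge ({i},{j}) already present")
    return _copy_with_edges(net, net.edges() + [(i, j)])


def remove_edge(net: StructuralNetwork, i: int, j: int) -> StructuralNetwork:
    """Return a copy of ``net`` with the present edge (i, j) removed."""
    if not net.has_edge(i, j):
        raise ValueError(f"edge ({i},{j}) not present")
    target = tuple(sorted((i, j)))
    return _copy_with_edges(net, [e for e in net.edges() if e != target])


def _sample_powerlaw_degrees(config: NetworkGenConfig,
                             rng: np.random.Generator) -> np.ndarray:
    ks = np.arange(config.k_min, config.k_max + 1)
    p = ks.astype(float) ** (-config.gamma)
    p /= p.sum()
    deg = rng.choice(ks, size=config.n, p=p)
    if deg.sum() % 2 == 1:
        # handshake lemma: resample one entry until the total is even
        while True:
            i = rng.integers(config.n)
            deg[i] = rng.choice(ks, p=p)
            if deg.sum() % 2 == 0:
                break
    return deg


def powerlaw_configuration(config: NetworkGenConfig) -> StructuralNetwork:
    """Scale-free graph via the configuration model.

    Degrees are drawn i.i.d. from p(k) ~ k^-gamma truncated to
    [k_min, k_max], realized by random stub matching, then simplified by
    dropping self-loops and collapsing multi-edges (so realized degrees
    are approximate).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    deg = _sample_powerlaw_degrees(config, rng)
    # stub matching: random perfect matching of the degree stubs
    stubs = np.repeat(np.arange(config.n), deg)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    edges = {tuple(sorted(p)) for p in pairs if p[0] != p[1]}
    return StructuralNetwork(config.n, sorted(edges))


def erdos_renyi_baseline(functional, seed: int):
    """Random-baseline rewiring of a functional network.

    Keeps the node set and the exact edge count but places the edges
    uniformly at random among distinct pairs (the G(n, M) model).  Used to
    judge whether functionally connected cells are closer in structural
    centrality than chance predicts.
    """
    from .synchrony import FunctionalNetwork  # local import: avoids a cycle

    n = functional.n_nodes
    m = len(functional.edges())
    max_edges = n * (n - 1) // 2
    if m > max_edges:
        raise ValueError(f"{m} edges do not fit on {n} nodes")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(max_edges, size=m, replace=False)
    # map linear index k to the pair (i, j), i < j, in lexicographic order
    iu, ju = np.triu_indices(n, k=1)
    edges = [(int(iu[k]), int(ju[k])) for k in chosen]
    return FunctionalNetwork.from_edges(n, edges, theta=functional.theta)


# -- file IO -----------------------------------------------------------

def write_edgelist(net: StructuralNetwork, path: str | Path) -> None:
    """Whitespace-delimited edge list; isolated nodes kept via a header."""
    lines = [f"# nodes {net.n_nodes}"]
    lines += [f"{i} {j}" for i, j in net.edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path: str | Path) -> StructuralNetwork:
    n_nodes = None
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "nodes":
                n_nodes = int(parts[1])
            continue
        i, j = line.split()
        edges.append((int(i), int(j)))
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in edges), default=0)
    return StructuralNetwork(n_nodes, edges)


def write_graphml(net: StructuralNetwork, path: str | Path) -> None:
    g = net.to_networkx()
    for i, lab in net.labels.items():
        g.nodes[i]["label"] = lab
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> StructuralNetwork:
    g = nx.read_graphml(str(path), node_type=int)
    labels = {i: d["label"] for i, d in g.nodes(data=True) if "label" in d}
    return StructuralNetwork(g.number_of_nodes(), list(g.edges()), labels or None)
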