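"""Structural-network centralities and functional-vs-structural statistics.

Four node centralities are used: degree, closeness, betweenness and
eigenvector.  Closeness uses the component-corrected normalized
(Wasserman-Faust) form, so it stays defined on disconnected graphs and
lives on a 0..1 scale; betweenness is normalized by the pair count
excluding endpoints; eigenvector centrality is the principal adjacency
eigenvector computed per connected component by power iteration and
scaled so the global maximum is 1.

To relate a functional network to structral-network centrality values
``v`` we average |v_i - v_j| over functional edges:

    M = sum_{(i,j) in E} |v_i - v_j| / |E|

Small M means functionally connected cells are alike in that centrality.
Each functional network is compared against an Erdos-Renyi rewiring of
its own edges (same node set, same edge count) with a paired Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network_builder import StructuralNetwork, erdos_renyi_baseline

__all__ = [
    "CentralityReport",
    "MetricComparison",
    "centralities",
    "centrality_difference",
    "compare_to_baseline",
    "centrality_density",
    "degree_density_correlation",
]

_POWER_TOL = 1e-10
_CENTRALITY_NAMES = ("degree", "closeness", "betweenness", "eigenvector")


def _eigenvector_per_component(g: nx.Graph, n: int) -> np.ndarray:
    """Principal adjacency eigenvector per component, global max scaled to 1.

    Power iteration with tolerance 1e-10 on each component's adjacency
    block, shifted by the identity (A + I has the same eigenvectors but a
    strictly dominant top eigenvalue, so the iteration also converges on
    bipartite components whose spectrum is symmetric).  Within a
    component the vector is L2-normalized (non-negative by
    Perron-Frobenius); the concatenated vector is divided by its global
    maximum.  Isolated nodes score 0.
    """
    out = np.zeros(n)
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            continue
        a = nx.to_numpy_array(g, nodelist=nodes) + np.eye(len(nodes))
        v = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
        for _ in range(10_000):
            w = a @ v
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            if np.max(np.abs(w - v)) < _POWER_TOL:
                v = w
                break
            v = w
        out[nodes] = np.abs(v)
    m = out.max()
    return out / m if m > 0 else out


def centralities(net: StructuralNetwork) -> "CentralityReport":
    """Degree, closeness, betweenness and eigenvector centrality per node."""
    if net.n_nodes < 1:
        raise ValueError("empty graph")
    g = net.to_networkx()
    n = net.n_nodes
    closeness = np.array(
        [nx.closeness_centrality(g, u, wf_improved=True) for u in range(n)]
    )
    betweenness_map = nx.betweenness_centrality(g, normalized=True, endpoints=False)
    betweenness = np.array([betweenness_map[u] for u in range(n)])
    return CentralityReport(
        degree=net.degrees().astype(float),
        closeness=closeness,
        betweenness=betweenness,
        eigenvector=_eigenvector_per_component(g, n),
    )


@dataclass
class CentralityReport:
    """Per-node centralities of one structural network."""

    degree: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray
    eigenvector: np.ndarray
    network_id: str | None = None

    def values(self, metric: str) -> np.ndarray:
        if metric not in _CENTRALITY_NAMES:
            raise ValueError(f"unknown centrality {metric!r}")
        return getattr(self, metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: getattr(self, name) for name in _CENTRALITY_NAMES}
        ).rename_axis("node")

    def densities(self, metric: str) -> np.ndarray:
        return centrality_density(self.values(metric))


def centrality_difference(functional, values: np.ndarray) -> float:
    """Mean |v_i - v_j| over the functional network's edges (the M metric)."""
    edges = functional.edges() if hasattr(functional, "edges") else list(functional)
    if len(edges) == 0:
        raise ValueError("functional network has no edges; M is undefined")
    values = np.asarray(values, dtype=float)
    e = np.asarray(edges)
    return float(np.mean(np.abs(values[e[:, 0]] - values[e[:, 1]])))


@dataclass
class MetricComparison:
    """Paired M values for functional networks and their random baselines."""

    metric: str
    m_functional: np.ndarray
    m_baseline: np.ndarray
    statistic: float
    pvalue: float
    degenerate: bool = False
    n_skipped: int = 0

    @property
    def median_functional(self) -> float:
        return float(np.median(self.m_functional))

    @property
    def median_baseline(self) -> float:
        return float(np.median(self.m_baseline))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"M_functional": self.m_functional, "M_baseline": self.m_baseline}
        ).rename_axis("trial")


def compare_to_baseline(functionals, values: np.ndarray, metric: str = "closeness",
                        seed=0, baseline_factory=None) -> MetricComparison:
    """M of each functional network vs its Erdos-Renyi rewiring, paired Wilcoxon.

    ``values`` are the per-node structural centralities the metric is
    computed with.  Each functional network gets its own baseline (edge
    count preserved, edges uniform at random); ``baseline_factory`` is a
    test hook replacing the rewiring.  Networks with no edges are skipped
    (M is undefined for them) and counted in ``n_skipped``.
    """
    functionals = list(functionals)
    if len(functionals) < 2:
        raise ValueError("need at least two functional networks")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    m_f, m_b = [], []
    n_skipped = 0
    for fnet, child in zip(functionals, ss.spawn(len(functionals))):
        if fnet.n_edges == 0:
            n_skipped += 1
            continue
        if baseline_factory is None:
            base = erdos_renyi_baseline(fnet, child)
        else:
            base = baseline_factory(fnet)
        m_f.append(centrality_difference(fnet, values))
        m_b.append(centrality_difference(base, values))
    m_f = np.asarray(m_f)
    m_b = np.asarray(m_b)
    if len(m_f) < 2:
        raise ValueError("fewer than two functional networks with edges")
    diffs = m_f - m_b
    if np.all(diffs == 0):
        return MetricComparison(metric, m_f, m_b, statistic=np.nan, pvalue=1.0,
                                degenerate=True, n_skipped=n_skipped)
    res = stats.wilcoxon(m_f, m_b, alternative="two-sided")
    return MetricComparison(metric, m_f, m_b, statistic=float(res.statistic),
                            pvalue=float(res.pvalue), n_skipped=n_skipped)


def centrality_density(values: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) of the node values, at each node.

    A node with high density is "typical" of the network in that
    centrality.  A zero-variance sample is degenerate: a warning is
    issued and all nodes get density 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two nodes")
    if np.ptp(values) == 0.0:
        warnings.warn("zero-variance centrality sample; densities degenerate",
                      RuntimeWarning, stacklevel=2)
        return np.ones_like(values)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    return kde(values)


def degree_density_correlation(functional_degrees, densities,
                               method: str = "pearson") -> tuple[float, float]:
    """Correlation (r, p) between functional degree and a centrality density."""
    x = np.asarray(functional_degrees, dtype=float)
    y = np.asarray(densities, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero-variance sample; correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)
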