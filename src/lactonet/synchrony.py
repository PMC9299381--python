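"""Burst detection, the pairwise similarity index, and functional networks.

A cell is "active" while its membrane potential sits above a fixed
threshold (default -40 mV, midway between the silent phase near -60/-75 mV
and the depolarized plateau near -20 mV; the pseudo-plateau stays above
threshold through its small spikes, so no debouncing is applied).

For two cells with total active durations T_i and T_j overlapping for
T_ij within the analysis window, the similarity is

    S_ij = T_ij / sqrt(T_i * T_j)

which is 1 for identical burst trains and 0 for disjoint ones (and 0 by
convention when either cell never bursts).  A functional network draws an
edge wherever S_ij exceeds a threshold theta (0.99 for near-perfect
synchrony; 0.85 for the relaxed criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ActivePhases",
    "FunctionalNetwork",
    "detect_active_phases",
    "similarity",
    "build_functional_network",
    "classify_pair_state",
    "classify_multiarm_state",
    "DEFAULT_V_THRESHOLD",
]

DEFAULT_V_THRESHOLD = -40.0  # mV


@dataclass
class ActivePhases:
    """Active-phase intervals [start, end) of one cell, in ms.

    ``duration`` is the summed interval length; each sample above
    threshold contributes one ``dt`` so duration never exceeds the window
    length.
    """

    starts: np.ndarray
    ends: np.ndarray
    window: tuple[float, float]   # [t_first_sample, t_last_sample + dt)
    dt: float

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts/ends length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must have positive length")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("intervals must be sorted")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("intervals must be disjoint")

    @property
    def duration(self) -> float:
        """Total active time T_i (ms)."""
        return float(np.sum(self.ends - self.starts))

    @property
    def n_intervals(self) -> int:
        return len(self.starts)


def detect_active_phases(t: np.ndarray, V: np.ndarray,
                         threshold: float = DEFAULT_V_THRESHOLD) -> ActivePhases:
    """Threshold-crossing burst detection on a uniformly sampled trace.

    A sample with V > threshold is active; maximal runs of active samples
    become intervals ``[t_first, t_last + dt)`` so durations are sample
    counts times dt.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t.ndim != 1 or V.shape != t.shape or len(t) == 0:
        raise ValueError("need matching non-empty 1-D time and voltage arrays")
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite voltage trace")
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    active = V > threshold
    # run boundaries via sign changes of the padded indicator
    padded = np.concatenate([[False], active, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    first = edges[0::2]       # index of first active sample of each run
    last = edges[1::2] - 1    # index of last active sample
    return ActivePhases(
        starts=t[first],
        ends=t[last] + dt,
        window=(float(t[0]), float(t[-1]) + dt),
        dt=dt,
    )


def _overlap_duration(a: ActivePhases, b: ActivePhases) -> float:
    """Exact total intersection length of two disjoint sorted interval sets."""
    if a.n_intervals == 0 or b.n_intervals == 0:
        return 0.0
    lo = np.maximum(a.starts[:, None], b.starts[None, :])
    hi = np.minimum(a.ends[:, None], b.ends[None, :])
    return float(np.sum(np.clip(hi - lo, 0.0, None)))


def similarity(phases_i: ActivePhases, phases_j: ActivePhases) -> float:
    """Similarity S_ij = T_ij / sqrt(T_i * T_j); 0 if either cell is silent."""
    if not np.allclose(phases_i.window, phases_j.window):
        raise ValueError("active phases computed on different analysis windows")
    T_i, T_j = phases_i.duration, phases_j.duration
    if T_i == 0.0 or T_j == 0.0:
        return 0.0
    return _overlap_duration(phases_i, phases_j) / np.sqrt(T_i * T_j)


@dataclass
class FunctionalNetwork:
    """Synchrony graph: edges are cell pairs with S_ij above threshold.

    ``S`` is the symmetric similarity matrix (diagonal ignored); for
    baseline/rewired networks built directly from an edge list it is None.
    """

    n_nodes: int
    theta: float
    S: np.ndarray | None = None
    _edges: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_similarity(cls, S: np.ndarray, theta: float) -> "FunctionalNetwork":
        S = np.asarray(S, dtype=float)
        n = S.shape[0]
        if S.shape != (n, n) or not np.allclose(S, S.T):
            raise ValueError("S must be a square symmetric matrix")
        iu, ju = np.triu_indices(n, k=1)
        keep = S[iu, ju] > theta
        edges = [(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])]
        return cls(n_nodes=n, theta=theta, S=S, _edges=edges)

    @classmethod
    def from_edges(cls, n_nodes: int, edges, theta: float = np.nan) -> "FunctionalNetwork":
        norm = sorted({tuple(sorted((int(i), int(j)))) for i, j in edges})
        for i, j in norm:
            if i == j or not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(f"invalid edge ({i},{j})")
        return cls(n_nodes=n_nodes, theta=theta, _edges=norm)

    def edges(self) -> list[tuple[int, int]]:
        return list(self._edges)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def degrees(self) -> np.ndarray:
        """Per-node functional degree."""
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self._edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, j in self._edges:
            attrs = {"S": float(self.S[i, j])} if self.S is not None else {}
            g.add_edge(i, j, **attrs)
        return g

    def clusters(self) -> list[frozenset[int]]:
        """Connected components restricted to nodes with >= 1 edge."""
        g = self.to_networkx()
        g.remove_nodes_from([v for v in g if g.degree(v) == 0])
        return [frozenset(c) for c in nx.connected_components(g)]

    def is_complete(self) -> bool:
        return self.n_edges == self.n_nodes * (self.n_nodes - 1) // 2

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def similarity_frame(self) -> pd.DataFrame:
        if self.S is None:
            raise ValueError("no similarity matrix attached")
        return pd.DataFrame(self.S)


def pairwise_similarity(t: np.ndarray, V: np.ndarray,
                        v_threshold: float = DEFAULT_V_THRESHOLD) -> np.ndarray:
    """Similarity matrix of all cell pairs from a (n_samples, n_cells) V array."""
    V = np.asarray(V, dtype=float)
    n_cells = V.shape[1]
    phases = [detect_active_phases(t, V[:, i], v_threshold) for i in range(n_cells)]
    S = np.eye(n_cells)
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            S[i, j] = S[j, i] = similarity(phases[i], phases[j])
    return S


def build_functional_network(trajectory, theta: float,
                             v_threshold: float = DEFAULT_V_THRESHOLD,
                             ) -> FunctionalNetwork:
    """Functional network of one trial from its analysis-window voltages.

    ``trajectory`` is a :class:`~lactonet.simulator.Trajectory` (or any
    object with ``t`` and 2-D ``V``).
    """
    S = pairwise_similarity(trajectory.t, trajectory.V, v_threshold)
    return FunctionalNetwork.from_similarity(S, theta)


def classify_pair_state(trajectory, theta: float = 0.99,
                        v_threshold: float = DEFAULT_V_THRESHOLD) -> str:
    """Asymptotic state of a two-cell run: 'synchronized' or 'antiphase'.

    The two coupled attractors of the pair are near-perfect synchrony and
    alternating (antiphase) bursting; everything below the synchrony
    threshold is classified antiphase.
    """
    V = np.asarray(trajectory.V)
    if V.ndim != 2 or V.shape[1] != 2:
        raise ValueError("pair classification needs a 2-cell trajectory")
    S = pairwise_similarity(trajectory.t, V, v_threshold)
    return "synchronized" if S[0, 1] > theta else "antiphase"


def classify_multiarm_state(functional: FunctionalNetwork, rings) -> str:
    """Synchrony pattern of a multi-arm trial.

    - ``complete``: the functional graph is complete.
    - ``ring``: the synchrony clusters are exactly the concentric rings
      (the center is unsynchronized or alone).
    - ``subgraph``: every cluster is a strict subset of a single ring.
    - ``other``: anything else (including a fully desynchronized trial).
    """
    rings = [frozenset(r) for r in rings]
    covered = frozenset().union(*rings) | {0} if rings else frozenset()
    n_ring_nodes = sum(len(r) for r in rings)
    if len(covered) != n_ring_nodes + 1 or functional.n_nodes != n_ring_nodes + 1:
        raise ValueError("ring partition does not match the functional node set")
    if functional.is_complete():
        return "complete"
    clusters = functional.clusters()
    if set(clusters) == set(rings):
        return "ring"
    if clusters and all(
        any(cl < ring for ring in rings) for cl in clusters
    ):
        return "subgraph"
    return "other"
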