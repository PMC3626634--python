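"""Weighted functional graphs and their topology measures.

The functional graph has the 19 electrodes as nodes and coherence values
as undirected edge weights.  Edge strength w maps to a *functional
distance* d = -ln(w): perfect synchrony (w = 1) has distance 0 and
incoherent pairs (w = 0) are infinitely distant.  Shortest-path lengths
are sums of edge distances along a path.

Measures (all on the fully weighted graph, no thresholding):

* characteristic path length — mean shortest functional distance over all
  unordered node pairs (infinite for a disconnected graph; driven by the
  weak, long connections);
* global efficiency — mean *inverse* shortest distance, with unreachable
  pairs contributing 0 (finite even when disconnected; driven by the
  strong, short connections);
* clustering coefficient — network mean of the geometric-mean (Onnela)
  weighted clustering, with coherence weights used as-is since they are
  already bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .coherence import BandCoherenceMatrix

__all__ = [
    "FunctionalGraph",
    "GraphMetrics",
    "build_graph",
    "shortest_distances",
    "characteristic_path_length",
    "clustering_coefficient",
    "global_efficiency",
    "graph_metrics",
]

#: distance floor for w = 1 edges (keeps 1/d finite at 1/EPS)
EPS = 1e-12


@dataclass
class FunctionalGraph:
    """Undirected weighted graph on the montage nodes."""

    nodes: list[str]
    weights: np.ndarray    # symmetric, in [0, 1], zero diagonal
    distances: np.ndarray  # -ln(weights), inf where weight is 0

    @property
    def n(self) -> int:
        return len(self.nodes)


def build_graph(m: BandCoherenceMatrix | np.ndarray,
                nodes: list[str] | None = None) -> FunctionalGraph:
    """Build the functional graph from a band coherence matrix."""
    if isinstance(m, BandCoherenceMatrix):
        values = np.array(m.values, dtype=float)
    else:
        values = np.array(m, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("coherence matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("coherence matrix must be symmetric")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("edge weights must lie in [0, 1]")
    weights = values.copy()
    np.fill_diagonal(weights, 0.0)
    with np.errstate(divide="ignore"):
        distances = -np.log(weights)
    np.fill_diagonal(distances, 0.0)
    if nodes is None:
        nodes = [f"n{i}" for i in range(values.shape[0])]
    return FunctionalGraph(list(nodes), weights, distances)


def shortest_distances(g: FunctionalGraph) -> np.ndarray:
    """All-pairs shortest functional distances (Dijkstra).

    Zero-distance edges (w = 1) are floored at EPS so the sparse-graph
    routine never confuses them with absent edges; infinite distances
    (w = 0) are genuine non-edges.
    """
    d = np.maximum(g.distances, EPS)
    np.fill_diagonal(d, 0.0)
    d[np.isinf(d)] = 0.0  # dense convention: 0 off-diagonal = no edge
    return shortest_path(d, method="D", directed=False)


def _pair_values(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def characteristic_path_length(g: FunctionalGraph,
                               sp: np.ndarray | None = None) -> float:
    """Mean shortest functional distance over unordered pairs
    (inf if any pair is unreachable)."""
    sp = shortest_distances(g) if sp is None else sp
    return float(_pair_values(sp).mean())


def global_efficiency(g: FunctionalGraph,
                      sp: np.ndarray | None = None) -> float:
    """Mean inverse shortest distance; unreachable pairs contribute 0."""
    sp = shortest_distances(g) if sp is None else sp
    d = _pair_values(sp)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[np.isinf(d)] = 0.0
    return float(inv.mean())


def clustering_coefficient(g: FunctionalGraph) -> float:
    """Network mean of Onnela geometric-mean weighted clustering.

    C_i = Σ_{j,h} (w_ij w_ih w_jh)^{1/3} / (k_i (k_i - 1)), with k_i the
    number of nonzero-weight neighbors; C_i = 0 when k_i < 2.
    """
    w = np.cbrt(g.weights)
    cube = np.diag(w @ w @ w)  # 2x number of closed triangles through i
    k = (g.weights > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, cube / denom, 0.0)
    return float(ci.mean())


@dataclass(frozen=True)
class GraphMetrics:
    characteristic_path_length: float
    clustering_coefficient: float
    global_efficiency: float


def graph_metrics(g: FunctionalGraph) -> GraphMetrics:
    sp = shortest_distances(g)
    return GraphMetrics(
        characteristic_path_length=characteristic_path_length(g, sp),
        clustering_coefficient=clustering_coefficient(g),
        global_efficiency=global_efficiency(g, sp),
    )
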