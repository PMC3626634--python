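"""Node-removal resilience and hub concentration.

Attacks and failures are simulated by deleting nodes (with their edges)
and recomputing global efficiency on the damaged graph; resilience at k
removed nodes is the ratio E_damaged / E_baseline.  *Targeted attack*
removes the k strongest nodes (node strength = sum of incident coherence
weights — binary degree is constant on a fully weighted graph, so strength
is the meaningful ranking), ranked once on the intact graph with ties
broken by montage order.  *Random failure* removes uniformly drawn
k-subsets and reports the mean and SD of the ratio across replicates.

Hub concentration is profiled as the normalized degree of the top-ranked
nodes: strength of the rank-r node divided by the total strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import FunctionalGraph, build_graph, global_efficiency

__all__ = [
    "ResilienceProfile",
    "HubProfile",
    "node_strengths",
    "targeted_attack",
    "random_failure",
    "hub_normalized_degree",
    "hub_profile",
]


@dataclass
class ResilienceProfile:
    mode: str                      # "targeted" | "random"
    ks: list[int]
    relative_efficiency: np.ndarray
    sd: np.ndarray | None = None       # random mode
    replicates: int | None = None      # random mode
    removal_order: list[str] | None = None  # targeted mode


@dataclass(frozen=True)
class HubProfile:
    rank: int
    node: str
    normalized_degree: float


def node_strengths(g: FunctionalGraph) -> np.ndarray:
    """Weighted degree (sum of incident coherence weights) per node."""
    return g.weights.sum(axis=1)


def _strength_ranking(g: FunctionalGraph) -> np.ndarray:
    """Node indices by decreasing strength; ties keep montage order."""
    s = node_strengths(g)
    return np.argsort(-s, kind="stable")


def _subgraph_efficiency(g: FunctionalGraph, keep: np.ndarray) -> float:
    sub = build_graph(g.weights[np.ix_(keep, keep)],
                      [g.nodes[i] for i in keep])
    return global_efficiency(sub)


def _baseline(g: FunctionalGraph) -> float:
    e0 = global_efficiency(g)
    if e0 <= 0:
        raise ValueError("baseline global efficiency is zero — "
                         "resilience undefined")
    return e0


def targeted_attack(g: FunctionalGraph, k_max: int = 5, *,
                    sequential: bool = False) -> ResilienceProfile:
    """Remove the top-k strongest nodes simultaneously for k = 1..k_max.

    With ``sequential=True`` the ranking is recomputed after each removal
    instead of being fixed on the intact graph.
    """
    if k_max >= g.n:
        raise ValueError("k_max must be smaller than the node count")
    e0 = _baseline(g)
    if k_max == 0:  # degenerate call: nothing removed
        return ResilienceProfile("targeted", [0], np.array([1.0]),
                                 removal_order=[])
    rel = np.empty(k_max)
    if not sequential:
        order = _strength_ranking(g)
        removed_names = [g.nodes[i] for i in order[:k_max]]
        for k in range(1, k_max + 1):
            keep = np.setdiff1d(np.arange(g.n), order[:k])
            rel[k - 1] = _subgraph_efficiency(g, keep) / e0
    else:
        removed: list[int] = []
        removed_names = []
        current = g
        mapping = np.arange(g.n)
        for k in range(1, k_max + 1):
            top = _strength_ranking(current)[0]
            removed.append(int(mapping[top]))
            removed_names.append(g.nodes[removed[-1]])
            keep = np.setdiff1d(np.arange(g.n), removed)
            mapping = keep
            current = build_graph(g.weights[np.ix_(keep, keep)],
                                  [g.nodes[i] for i in keep])
            rel[k - 1] = global_efficiency(current) / e0
    return ResilienceProfile("targeted", list(range(1, k_max + 1)), rel,
                             removal_order=removed_names)


def random_failure(g: FunctionalGraph, k_max: int = 5,
                   replicates: int = 1000,
                   seed: int | np.random.Generator = 0) -> ResilienceProfile:
    """Efficiency ratio after removing uniform random k-subsets."""
    if k_max >= g.n:
        raise ValueError("k_max must be smaller than the node count")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    e0 = _baseline(g)
    mean = np.empty(k_max)
    sd = np.empty(k_max)
    nodes = np.arange(g.n)
    for k in range(1, k_max + 1):
        ratios = np.empty(replicates)
        for r in range(replicates):
            drop = rng.choice(nodes, size=k, replace=False)
            keep = np.setdiff1d(nodes, drop)
            ratios[r] = _subgraph_efficiency(g, keep) / e0
        mean[k - 1] = ratios.mean()
        sd[k - 1] = ratios.std(ddof=1) if replicates > 1 else 0.0
    return ResilienceProfile("random", list(range(1, k_max + 1)), mean,
                             sd=sd, replicates=replicates)


def hub_normalized_degree(g: FunctionalGraph, rank: int) -> HubProfile:
    """Strength of the rank-th strongest node over the total strength."""
    if not 1 <= rank <= g.n:
        raise ValueError("rank out of range")
    s = node_strengths(g)
    order = _strength_ranking(g)
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero graph has no hub profile")
    i = order[rank - 1]
    return HubProfile(rank, g.nodes[i], float(s[i] / total))


def hub_profile(g: FunctionalGraph, ranks=(1, 2, 3)) -> list[HubProfile]:
    return [hub_normalized_degree(g, r) for r in ranks]
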