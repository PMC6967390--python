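"""Distance-based diagnostics on the inferred network.

Checks whether positively labeled families cluster (shortest-path distance to
the nearest other positive vs. random same-size node sets) and assigns
putative subtypes from typed known families within two hops.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, deque
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from .profiles import Label

logger = logging.getLogger(__name__)

__all__ = [
    "distances_to_labeled",
    "clustering_statistic",
    "ClusteringResult",
    "TypeAssignment",
    "assign_putative_type",
]

INF = math.inf


def _multi_source_bfs(G: nx.Graph, sources) -> Dict[str, float]:
    dist = {node: INF for node in G.nodes}
    queue = deque()
    for s in sources:
        dist[s] = 0
        queue.append(s)
    while queue:
        u = queue.popleft()
        for v in G.adj[u]:
            if dist[v] == INF:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def distances_to_labeled(G: nx.Graph, labels: Mapping[str, Label]) -> Dict[str, float]:
    """Hop distance from every node to the nearest POSITIVE node (inf if none reachable)."""
    positives = [n for n in G.nodes if labels.get(n) == Label.POSITIVE]
    if not positives:
        raise ValueError("graph has no POSITIVE nodes")
    return _multi_source_bfs(G, positives)


def _mean_nearest_within(G: nx.Graph, members) -> Tuple[float, int]:
    """Mean over members of hop distance to the nearest *other* member.

    Unreachable members are excluded from the mean; their count is returned.
    """
    members = list(members)
    dists = []
    unreachable = 0
    member_set = set(members)
    for m in members:
        d = _multi_source_bfs(G, member_set - {m})[m]
        if math.isinf(d):
            unreachable += 1
        else:
            dists.append(d)
    mean = float(np.mean(dists)) if dists else INF
    return mean, unreachable


@dataclass(frozen=True)
class ClusteringResult:
    observed: float
    null_means: np.ndarray
    p_value: float
    n_excluded_unreachable: int


def clustering_statistic(
    G: nx.Graph,
    labels: Mapping[str, Label],
    n_draws: int = 1000,
    seed: int = 0,
) -> ClusteringResult:
    """Do POSITIVE nodes sit closer to each other than random node sets?

    Observed statistic: mean over POSITIVE nodes of the hop distance to the
    nearest other POSITIVE node.  Null: the same statistic for ``n_draws``
    uniform random node subsets of the same size.  The empirical p-value uses
    the add-one rule, so it is never zero.
    """
    positives = [n for n in G.nodes if labels.get(n) == Label.POSITIVE]
    if len(positives) < 2:
        raise ValueError("need at least 2 POSITIVE nodes")
    observed, excluded = _mean_nearest_within(G, positives)
    if excluded:
        logger.info("%d POSITIVE nodes unreachable from any other; excluded", excluded)
    rng = np.random.default_rng(seed)
    nodes = list(G.nodes)
    null = np.empty(n_draws)
    for r in range(n_draws):
        subset = rng.choice(nodes, size=len(positives), replace=False)
        null[r], _ = _mean_nearest_within(G, subset)
    p = (1 + int(np.sum(null <= observed))) / (1 + n_draws)
    return ClusteringResult(observed, null, p, excluded)


@dataclass(frozen=True)
class TypeAssignment:
    family_id: str
    subtype: Optional[str]
    confidence: str  # CONFIDENT | SINGLE_NEIGHBOR | NONE
    n_supporting: int


def assign_putative_type(
    G: nx.Graph, node: str, type_map: Mapping[str, str]
) -> TypeAssignment:
    """Assign a subtype from typed known families within two hops.

    The modal subtype with count >= 2 wins (CONFIDENT); exactly one typed
    neighbor in range yields SINGLE_NEIGHBOR; anything else, including a tie
    among modal subtypes, yields NONE.
    """
    if node not in G:
        raise ValueError(f"node {node!r} not in graph")
    within = nx.single_source_shortest_path_length(G, node, cutoff=2)
    typed = [type_map[n] for n in within if n != node and n in type_map]
    if not typed:
        return TypeAssignment(node, None, "NONE", 0)
    if len(typed) == 1:
        return TypeAssignment(node, typed[0], "SINGLE_NEIGHBOR", 1)
    counts = Counter(typed)
    (top, top_n), = counts.most_common(1)
    modal = [t for t, c in counts.items() if c == top_n]
    if len(modal) > 1:
        logger.info("type tie for %s: %s", node, sorted(modal))
        return TypeAssignment(node, None, "NONE", 0)
    if top_n >= 2:
        return TypeAssignment(node, top, "CONFIDENT", top_n)
    # unreachable: len(typed) >= 2 with unique modal implies top_n >= 2
    return TypeAssignment(node, None, "NONE", 0)  # pragma: no cover
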