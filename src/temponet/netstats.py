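"""Statistics over inferred per-time-point networks.

Degree is in-degree + out-degree over retained arcs; betweenness centrality
is unweighted shortest-path betweenness on the directed graph (unnormalised,
all shortest paths counted); the beta index is #edges / #nodes over nodes
incident to at least one retained arc; overlap reports give, for every
non-empty subset of time-points, the number of items exclusive to exactly
that subset (upset-plot semantics) alongside plain pairwise intersections.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import pandas as pd

from .bayesnet import StrengthNetwork
from .errors import InvalidParameterError

logger = logging.getLogger(__name__)


def to_digraph(network: StrengthNetwork, retained_only: bool = True) -> nx.DiGraph:
    """Retained arcs as a networkx DiGraph with node/edge attributes."""
    G = nx.DiGraph()
    arcs = network.retained_arcs() if retained_only else network.arcs
    nodes = sorted(set(arcs["source"]) | set(arcs["target"]))
    for n in nodes:
        G.add_node(n, type=network.node_types.get(n, "unknown"))
    for _, row in arcs.iterrows():
        G.add_edge(row["source"], row["target"], strength=float(row["strength"]))
    return G


def _dense_rank_desc(values: pd.Series) -> pd.Series:
    return values.rank(method="dense", ascending=False).astype(int)


def degree_stats(network: StrengthNetwork) -> pd.DataFrame:
    """Per-node degree and betweenness with descending dense ranks (ties share)."""
    G = to_digraph(network)
    bc = betweenness(network)
    rows = [
        {
            "node": n,
            "type": network.node_types.get(n, "unknown"),
            "timepoint": network.timepoint,
            "degree": G.in_degree(n) + G.out_degree(n),
            "betweenness": bc.get(n, 0.0),
        }
        for n in sorted(G.nodes)
    ]
    stats = pd.DataFrame(
        rows, columns=["node", "type", "timepoint", "degree", "betweenness"]
    )
    if not stats.empty:
        stats["degree_rank"] = _dense_rank_desc(stats["degree"])
        stats["betweenness_rank"] = _dense_rank_desc(stats["betweenness"])
    return stats


def betweenness(network: StrengthNetwork, directed: bool = True) -> dict[str, float]:
    """Unnormalised shortest-path betweenness centrality per node."""
    G = to_digraph(network)
    if not directed:
        G = G.to_undirected()
    return nx.betweenness_centrality(G, normalized=False)


def beta_index(network: StrengthNetwork) -> float:
    """#edges / #nodes, nodes restricted to those incident to a retained arc."""
    arcs = network.retained_arcs()
    nodes = set(arcs["source"]) | set(arcs["target"])
    if not nodes:
        if not network.node_types:
            raise InvalidParameterError("beta index undefined for an empty network")
        logger.warning("no retained arcs at %s; beta index 0", network.timepoint)
        return 0.0
    return len(arcs) / len(nodes)


def top_fraction_nodes(stats: pd.DataFrame, column: str, fraction: float = 0.20) -> set[str]:
    """Nodes in the top ``fraction`` by ``column`` (rank cutoff, ties included)."""
    if stats.empty:
        return set()
    k = max(1, int(round(fraction * len(stats))))
    cutoff = stats[column].sort_values(ascending=False).iloc[k - 1]
    return set(stats.loc[stats[column] >= cutoff, "node"])


def overlap_counts(item_sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive-intersection (upset) counts over a family of labelled sets.

    Each item is counted once, in the row for the maximal subset of labels
    whose sets all contain it; counts therefore sum to |union|.
    """
    if not item_sets:
        raise InvalidParameterError("need at least one set")
    labels = list(item_sets)
    membership: dict[object, tuple[str, ...]] = {}
    for item in set().union(*item_sets.values()):
        membership[item] = tuple(lab for lab in labels if item in item_sets[lab])
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            count = sum(1 for m in membership.values() if m == combo)
            rows.append(
                {"subset": "&".join(combo), "n_sets": r, "exclusive_count": count}
            )
    return pd.DataFrame(rows, columns=["subset", "n_sets", "exclusive_count"])


def pairwise_intersections(item_sets: dict[str, set]) -> pd.DataFrame:
    """Plain |A intersect B| for every unordered pair of labelled sets."""
    rows = [
        {"set_a": a, "set_b": b, "shared": len(item_sets[a] & item_sets[b])}
        for a, b in combinations(item_sets, 2)
    ]
    return pd.DataFrame(rows, columns=["set_a", "set_b", "shared"])


def edge_sets(networks: dict[str, StrengthNetwork]) -> dict[str, set[tuple[str, str]]]:
    """Retained (source, target) pairs per time-point, for edge-overlap reports."""
    return {tp: net.retained_pairs() for tp, net in networks.items()}


def membership_matrix(item_sets: dict[str, set]) -> pd.DataFrame:
    """Binary item x set membership matrix (input for external upset plotting).

    Edge items (ordered pairs) are rendered as ``source->target``.
    """
    items = sorted(set().union(*item_sets.values()), key=str)
    labels = ["->".join(i) if isinstance(i, tuple) else str(i) for i in items]
    return pd.DataFrame(
        {lab: [int(i in s) for i in items] for lab, s in item_sets.items()},
        index=pd.Index(labels, name="item"),
    )
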