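"""Hub-protein ranking by Maximal Clique Centrality (MCC).

For a module's induced protein-interaction subgraph, the MCC of a node v is

    MCC(v) = sum over maximal cliques C containing v, |C| >= 2, of (|C|-1)!

Isolated nodes (no clique of size >= 2) score 0. Maximal cliques are
enumerated with the Bron-Kerbosch pivoting algorithm. Ranks are
deterministic: descending score, ties broken by ascending protein ID.
"""

from __future__ import annotations

from math import factorial

import networkx as nx
import pandas as pd

from .io import InteractionNetwork
from .wgcna import ModulePartition

__all__ = ["build_module_network", "maximal_cliques", "mcc_scores", "top_hubs"]


def build_module_network(
    partition: ModulePartition, net: InteractionNetwork, module: int
) -> nx.Graph:
    """Induced subgraph of the interaction network on a module's proteins.

    Module proteins absent from the network appear as isolated nodes.
    """
    if module not in partition.module_ids:
        raise ValueError(f"unknown module label: {module}")
    members = partition.members(module)
    g = nx.Graph()
    g.add_nodes_from(members)
    member_set = set(members)
    for u, v in net.graph.subgraph(member_set).edges():
        g.add_edge(u, v)
    return g


def maximal_cliques(g: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques of size >= 2, canonically ordered."""
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= 2]
    return sorted(cliques)


def mcc_scores(g: nx.Graph) -> pd.DataFrame:
    """MCC score, rank and top-k flag placeholder for every node."""
    scores = {v: 0 for v in g.nodes}
    for clique in maximal_cliques(g):
        w = factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    table = pd.DataFrame(
        {"protein": list(scores), "mcc": list(scores.values())}
    ).sort_values(["mcc", "protein"], ascending=[False, True], kind="stable")
    table["rank"] = range(1, len(table) + 1)
    return table.reset_index(drop=True)


def top_hubs(table: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """First k rows by rank (all rows when the module is smaller than k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out = table.sort_values("rank").head(k).copy()
    return out.reset_index(drop=True)
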