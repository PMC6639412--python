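"""Hierarchical level of each cortical area from the adjacency graph.

The level eta of an area is the number of edges on the shortest path from
that area to the hemisphere's primary visual cortex (V1), computed with
Dijkstra's algorithm on unit edge weights (equivalent to BFS).  eta(V1) = 0
by default; ``level_offset`` shifts the convention.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def hierarchical_levels(edges: pd.DataFrame, root: str, level_offset: int = 0) -> pd.Series:
    """eta per area of the connected component containing ``root``.

    ``edges`` has columns area_a, area_b (undirected).  Raises on self-loops
    and lists any area of the component's node set that cannot reach the
    root (cannot happen within one component, but disconnected inputs are
    handled by :func:`levels_table`).
    """
    g = _graph(edges)
    if root not in g:
        raise ValueError(f"root {root!r} not in graph")
    dist = nx.single_source_dijkstra_path_length(g, root, weight=None)
    return pd.Series(
        {a: int(d) + level_offset for a, d in dist.items()}, name="eta"
    ).sort_index()


def _graph(edges: pd.DataFrame) -> nx.Graph:
    if len(edges) == 0:
        raise ValueError("empty edge list: no graph")
    loops = edges[edges["area_a"] == edges["area_b"]]
    if len(loops):
        raise ValueError(f"self-loops: {loops['area_a'].tolist()}")
    g = nx.Graph()
    g.add_edges_from(edges[["area_a", "area_b"]].itertuples(index=False, name=None))
    return g


def levels_table(
    edges: pd.DataFrame, roots=("L_V1", "R_V1"), level_offset: int = 0
) -> pd.DataFrame:
    """Levels for a multi-hemisphere graph, one root per component.

    Every area must be reachable from exactly one of the roots; unreachable
    areas raise an error listing them.
    """
    g = _graph(edges)
    levels: dict[str, int] = {}
    for root in roots:
        part = hierarchical_levels(edges, root, level_offset)
        for area, eta in part.items():
            if area in levels:
                raise ValueError(f"area {area!r} reachable from more than one root")
            levels[area] = eta
    unreachable = sorted(set(g.nodes) - set(levels))
    if unreachable:
        raise ValueError(f"areas unreachable from any root: {unreachable}")
    return (
        pd.DataFrame({"area": list(levels), "eta": list(levels.values())})
        .sort_values("area")
        .reset_index(drop=True)
    )
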