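"""Node-level centrality with the report conventions of UCINET-style SNA.

All three measures are reported on a 0–100 percent scale.  Degree
centrality offers two conventions: ``"neighbor"`` (default) counts a
node's unique neighbours in the symmetrized graph over n-1 — the
convention the worked-example table uses — while ``"eq2"`` averages
in- and out-degree over 2(n-1).  Betweenness and closeness default to
the symmetrized (undirected) graph, whose normalizations
2/((n-1)(n-2)) and (n-1)/farness are the classic Freeman forms; a
directed variant is available.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from .containers import DirectedNetwork

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "centrality_table",
]


def degree_centrality(net: DirectedNetwork, convention: str = "neighbor") -> pd.Series:
    """Percent degree centrality per node.

    ``"neighbor"``: 100 * |{j : a_ij or a_ji}| / (n-1).
    ``"eq2"``:      100 * (in_i + out_i) / (2 (n-1)).
    """
    n = net.n
    if n < 2:
        raise ValueError("degree centrality undefined for n < 2")
    if convention == "neighbor":
        vals = 100.0 * net.symmetrized().sum(axis=1) / (n - 1)
    elif convention == "eq2":
        vals = 100.0 * (net.in_degrees() + net.out_degrees()) / (2 * (n - 1))
    else:
        raise ValueError(f"unknown degree convention {convention!r}")
    return pd.Series(vals, index=net.labels, name="degree")


def betweenness_centrality(net: DirectedNetwork, symmetrize: bool = True) -> pd.Series:
    """Percent Freeman betweenness: 100 * 2 sum_{j<k} g_jk(i)/g_jk / (n^2-3n+2).

    Pair terms with no connecting path contribute zero.  Computed on the
    symmetrized graph by default; ``symmetrize=False`` uses directed
    shortest paths with the directed normalization (n-1)(n-2).
    """
    if net.n < 3:
        raise ValueError("betweenness normalization undefined for n < 3")
    g = net.to_networkx(directed=not symmetrize)
    bc = nx.betweenness_centrality(g, normalized=True)
    return pd.Series({v: 100.0 * bc[v] for v in net.labels}, name="betweenness")


def closeness_centrality(
    net: DirectedNetwork,
    symmetrize: bool = True,
    mode: str = "component",
):
    """Percent closeness: 100 * (n-1) / sum_j d_ij on a connected graph.

    For nodes that cannot reach every other node, ``mode="component"``
    (default) evaluates the formula within the node's reachable set
    (isolates score 0) and flags the node; ``mode="strict"`` scores any
    such node 0.  Returns ``(values, disconnected)`` as two aligned
    Series.
    """
    n = net.n
    if n < 2:
        raise ValueError("closeness undefined for n < 2")
    if mode not in ("component", "strict"):
        raise ValueError(f"unknown closeness mode {mode!r}")
    adj = net.symmetrized() if symmetrize else net.a
    d = csgraph.shortest_path(adj.astype(float), method="D", unweighted=True)
    vals = np.zeros(n)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        di = np.delete(d[i], i)
        reach = np.isfinite(di)
        k = int(reach.sum())
        if k == n - 1:
            vals[i] = 100.0 * (n - 1) / di.sum()
        else:
            flags[i] = True
            if mode == "component" and k > 0:
                vals[i] = 100.0 * k / di[reach].sum()
    return (
        pd.Series(vals, index=net.labels, name="closeness"),
        pd.Series(flags, index=net.labels, name="disconnected"),
    )


def centrality_table(
    net: DirectedNetwork,
    degree_convention: str = "neighbor",
    symmetrize: bool = True,
    decimals: int | None = 3,
) -> pd.DataFrame:
    """Per-node report table: in/out degree, degree, betweenness, closeness.

    ``decimals=None`` keeps full precision; the default rounds the
    percent columns to 3 decimals for report output.
    """
    cc, _ = closeness_centrality(net, symmetrize=symmetrize)
    table = pd.DataFrame(
        {
            "in_degree": pd.Series(net.in_degrees(), index=net.labels),
            "out_degree": pd.Series(net.out_degrees(), index=net.labels),
            "degree": degree_centrality(net, convention=degree_convention),
            "betweenness": betweenness_centrality(net, symmetrize=symmetrize),
            "closeness": cc,
        }
    )
    table.index.name = "region"
    if decimals is not None:
        for col in ("degree", "betweenness", "closeness"):
            table[col] = table[col].round(decimals)
    return table
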