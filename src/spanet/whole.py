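"""Whole-network structure: density, connectedness, hierarchy, efficiency.

Besides density, these are the classic Krackhardt (1994) graph-theoretic
dimensions of informal structure, the operationalization standard SNA
software reports:

* connectedness — the fraction of unordered node pairs joined by some
  path in the underlying undirected graph (accessibility of the
  network);
* hierarchy — among unordered pairs reachable in at least one direction
  of the directed reachability relation, the fraction that are *not*
  mutually reachable (how one-way the network's influence is);
* efficiency — one minus the proportion of redundant undirected edges,
  i.e. edges beyond a spanning tree of each component, relative to the
  maximum possible surplus (how lean the network is; low efficiency
  means many superimposed ties and a more stable network).

All four lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.sparse import csgraph

from .containers import DirectedNetwork

__all__ = [
    "WholeNetworkSummary",
    "density",
    "connectedness",
    "hierarchy",
    "efficiency",
    "summarize",
]


@dataclass
class WholeNetworkSummary:
    n_arcs: int
    density: float
    connectedness: float
    hierarchy: float
    efficiency: float

    def to_dict(self) -> dict:
        return asdict(self)


def density(net: DirectedNetwork) -> float:
    """Arc count over the n(n-1) possible directed ties."""
    n = net.n
    if n < 2:
        raise ValueError("density undefined for n < 2")
    return net.n_arcs / (n * (n - 1))


def _component_labels(net: DirectedNetwork) -> np.ndarray:
    _, labels = csgraph.connected_components(net.symmetrized(), directed=False)
    return labels


def connectedness(net: DirectedNetwork) -> float:
    """1 minus the fraction of node pairs with no connecting path
    (underlying undirected graph)."""
    n = net.n
    if n < 2:
        raise ValueError("connectedness undefined for n < 2")
    labels = _component_labels(net)
    sizes = np.bincount(labels)
    # pairs inside components are connected; cross-component pairs are not
    disconnected_pairs = (n * n - (sizes ** 2).sum()) / 2
    return 1.0 - disconnected_pairs / (n * (n - 1) / 2)


def _reachability(a: np.ndarray) -> np.ndarray:
    """Boolean transitive closure (excluding trivial self-reachability)."""
    n = a.shape[0]
    r = a.astype(bool)
    # repeated boolean squaring of (I | A)
    m = r | np.eye(n, dtype=bool)
    k = 1
    while k < n:
        m = (m.astype(np.uint8) @ m.astype(np.uint8)) > 0
        k *= 2
    r = m & ~np.eye(n, dtype=bool)
    return r


def hierarchy(net: DirectedNetwork) -> float:
    """Fraction of reachable unordered pairs that are one-way only.

    A pair counts as reachable if either node can reach the other along
    directed arcs; it counts as mutual if both can.  With no reachable
    pair at all the index is defined as 0.
    """
    if net.n < 2:
        raise ValueError("hierarchy undefined for n < 2")
    r = _reachability(net.a)
    either = r | r.T
    both = r & r.T
    n_either = either.sum() // 2
    if n_either == 0:
        return 0.0
    return 1.0 - (both.sum() // 2) / n_either


def efficiency(net: DirectedNetwork) -> float:
    """1 minus the proportion of redundant undirected edges.

    On the underlying graph with components of sizes n_c and L edges in
    total, a spanning forest needs sum(n_c - 1) edges; the surplus is
    measured against the maximum surplus sum(C(n_c,2) - (n_c - 1)).
    Defined as 1 when no surplus is possible (all components trees at
    most).
    """
    if net.n < 2:
        raise ValueError("efficiency undefined for n < 2")
    und = net.symmetrized()
    labels = _component_labels(net)
    sizes = np.bincount(labels)
    n_edges = und.sum() // 2
    spanning = (sizes - 1).sum()
    max_extra = (sizes * (sizes - 1) // 2 - (sizes - 1)).sum()
    if max_extra == 0:
        return 1.0
    return 1.0 - (n_edges - spanning) / max_extra


def summarize(net: DirectedNetwork) -> WholeNetworkSummary:
    """All four whole-network indices plus the arc count."""
    return WholeNetworkSummary(
        n_arcs=net.n_arcs,
        density=density(net),
        connectedness=connectedness(net),
        hierarchy=hierarchy(net),
        efficiency=efficiency(net),
    )
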