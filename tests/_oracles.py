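"""Independent brute-force oracles for small graphs.

Everything here works by exhaustive enumeration of simple paths or node
pairs, deliberately sharing no code with the package (which uses
networkx/scipy/boolean matrix algebra), so the two routes can be
compared on all digraphs small enough to enumerate.
"""

from __future__ import annotations


def simple_paths(adj, s, t):
    """All simple paths s -> t following arcs of a 0/1 matrix."""
    n = len(adj)
    out = []

    def dfs(node, visited, path):
        if node == t:
            out.append(list(path))
            return
        for nxt in range(n):
            if adj[node][nxt] and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    dfs(s, {s}, [s])
    return out


def shortest_paths(adj, s, t):
    """(distance, list of geodesics) or (None, []) if unreachable."""
    paths = simple_paths(adj, s, t)
    if not paths:
        return None, []
    dist = min(len(p) - 1 for p in paths)
    return dist, [p for p in paths if len(p) - 1 == dist]


def reachable(adj, s, t):
    return bool(simple_paths(adj, s, t)) if s != t else True


def symmetrize(a):
    n = len(a)
    return [[1 if (a[i][j] or a[j][i]) and i != j else 0 for j in range(n)]
            for i in range(n)]


def density(a):
    n = len(a)
    return sum(map(sum, a)) / (n * (n - 1))


def connectedness(a):
    und = symmetrize(a)
    n = len(a)
    bad = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if not reachable(und, i, j)
    )
    return 1.0 - bad / (n * (n - 1) / 2)


def hierarchy(a):
    n = len(a)
    either = both = 0
    for i in range(n):
        for j in range(i + 1, n):
            fwd = reachable(a, i, j)
            back = reachable(a, j, i)
            either += fwd or back
            both += fwd and back
    if either == 0:
        return 0.0
    return 1.0 - both / either


def efficiency(a):
    und = symmetrize(a)
    n = len(a)
    comp = [None] * n
    c = 0
    for i in range(n):
        if comp[i] is None:
            stack = [i]
            comp[i] = c
            while stack:
                u = stack.pop()
                for v in range(n):
                    if und[u][v] and comp[v] is None:
                        comp[v] = c
                        stack.append(v)
            c += 1
    sizes = [comp.count(k) for k in range(c)]
    n_edges = sum(und[i][j] for i in range(n) for j in range(i + 1, n))
    extra = n_edges - sum(s - 1 for s in sizes)
    max_extra = sum(s * (s - 1) // 2 - (s - 1) for s in sizes)
    if max_extra == 0:
        return 1.0
    return 1.0 - extra / max_extra


def betweenness_percent(a):
    """Freeman betweenness (percent) on the symmetrized graph."""
    und = symmetrize(a)
    n = len(a)
    vals = []
    for i in range(n):
        total = 0.0
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k):
                    continue
                _, geos = shortest_paths(und, j, k)
                if not geos:
                    continue
                through = sum(1 for p in geos if i in p[1:-1])
                total += through / len(geos)
        vals.append(100.0 * 2.0 * total / ((n - 1) * (n - 2)))
    return vals


def closeness_percent(a):
    """Percent closeness on the symmetrized graph, within each node's
    reachable set; isolates score 0."""
    und = symmetrize(a)
    n = len(a)
    vals = []
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            d, _ = shortest_paths(und, i, j)
            if d is not None:
                dists.append(d)
        if not dists:
            vals.append(0.0)
        elif len(dists) == n - 1:
            vals.append(100.0 * (n - 1) / sum(dists))
        else:
            vals.append(100.0 * len(dists) / sum(dists))
    return vals
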