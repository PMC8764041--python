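"""Independent brute-force oracles for graph metrics.

Deliberately naive implementations (triple loops, Floyd-Warshall, exhaustive
path enumeration, exhaustive partition search) used only to verify the
production code; they share no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def adjacency(graph) -> tuple[list, np.ndarray]:
    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in graph.edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = True
    return nodes, a


def clustering_brute(graph) -> float:
    """Mean local clustering, triangles counted by enumerating neighbor pairs."""
    nodes, a = adjacency(graph)
    n = len(nodes)
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        tri = sum(1 for x, y in itertools.combinations(nbrs, 2) if a[x, y])
        vals.append(tri / (k * (k - 1) / 2))
    return float(np.mean(vals))


def apl_floyd_warshall(graph) -> float:
    """Average shortest path over connected pairs via Floyd-Warshall."""
    nodes, a = adjacency(graph)
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    off = d[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise ValueError("no connected pairs")
    return float(finite.mean())


def betweenness_brute(graph) -> dict:
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    nodes, a = adjacency(graph)
    n = len(nodes)
    # all shortest-path distances
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]

    def shortest_paths(s, t):
        """All shortest s->t paths by depth-limited DFS with distance pruning."""
        limit = d[s, t]
        out = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                out.append(path)
                continue
            for w in range(n):
                if a[v, w] and w not in path and len(path) + d[w, t] <= limit:
                    stack.append((w, path + [w]))
        return out

    acc = dict.fromkeys(range(n), 0.0)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]):
            continue
        paths = shortest_paths(s, t)
        for p in paths:
            for v in p[1:-1]:
                acc[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {nodes[i]: acc[i] / norm for i in range(n)}


def set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_q(graph, blocks) -> float:
    """Newman-Girvan Q of a given partition."""
    m = graph.number_of_edges()
    q = 0.0
    for block in blocks:
        s = set(block)
        e_c = sum(1 for u, v in graph.edges if u in s and v in s)
        d_c = sum(graph.degree(v) for v in s)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def max_modularity_exhaustive(graph) -> float:
    """Max Q over every partition of the nodes (n <= 8)."""
    nodes = list(graph.nodes)
    assert len(nodes) <= 8, "exhaustive search limited to n <= 8"
    return max(modularity_q(graph, p) for p in set_partitions(nodes))
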