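"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid networkx/scipy shortcuts used by the package:
transitivity and path lengths come from adjacency counting and
Floyd-Warshall, modularity from exhaustive partition enumeration, and
hypergeometric tails from enumerating subset placements.
"""

from itertools import combinations

import numpy as np


def brute_transitivity(edges: list[tuple[int, int]], nodes: list[int]) -> float:
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    triangles = 0
    triples = 0
    for v in nodes:
        k = len(adj[v])
        triples += k * (k - 1) // 2  # connected triples centered at v
        for a, b in combinations(sorted(adj[v]), 2):
            if b in adj[a]:
                triangles += 1
    # each triangle counted once per center vertex => 3x; 3*tri/triples = (3*tri/3)/... keep raw
    if triples == 0:
        return 0.0
    return triangles / triples  # = 3*(#triangles)/(#triples) since triangles counted 3x


def brute_avg_path_length(edges: list[tuple[int, int]], nodes: list[int]) -> float:
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    inf = float("inf")
    d = np.full((n, n), inf)
    np.fill_diagonal(d, 0.0)
    for a, b in edges:
        d[index[a], index[b]] = 1.0
        d[index[b], index[a]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    iu = np.triu_indices(n, 1)
    finite = d[iu][np.isfinite(d[iu])]
    if finite.size == 0:
        return float("nan")
    return float(finite.mean())


def _set_partitions(items: list):
    """All set partitions via restricted growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    a = [0] * n
    b = [0] * n  # b[i] = max(a[0..i-1])
    while True:
        groups: dict[int, list] = {}
        for item, g in zip(items, a):
            groups.setdefault(g, []).append(item)
        yield list(groups.values())
        # next restricted growth string
        i = n - 1
        while i > 0 and a[i] == b[i] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0
        for j in range(1, n):
            b[j] = max(b[j - 1], a[j - 1])


def modularity_of(edges: list[tuple[int, int]], partition: list[list]) -> float:
    m = len(edges)
    if m == 0:
        return float("nan")
    comm = {}
    for ci, group in enumerate(partition):
        for v in group:
            comm[v] = ci
    ncomm = len(partition)
    e_in = [0] * ncomm
    deg = [0] * ncomm
    for a, b in edges:
        deg[comm[a]] += 1
        deg[comm[b]] += 1
        if comm[a] == comm[b]:
            e_in[comm[a]] += 1
    return sum(e_in[c] / m - (deg[c] / (2 * m)) ** 2 for c in range(ncomm))


def brute_max_modularity(edges: list[tuple[int, int]], nodes: list) -> float:
    best = -np.inf
    for part in _set_partitions(list(nodes)):
        q = modularity_of(edges, part)
        if q > best:
            best = q
    return float(best)


def brute_betweenness(edges: list[tuple[int, int]], nodes: list) -> dict:
    """Exact betweenness by enumerating all shortest paths (BFS path counting)."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    bet = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        # enumerate all shortest s-t paths by BFS layering
        from collections import deque

        dist = {s: 0}
        dq = deque([s])
        while dq:
            u = dq.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    dq.append(w)
        if t not in dist:
            continue
        paths: list[tuple] = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(tuple(path))
                return
            for w in adj[u]:
                if dist.get(w, -1) == dist[u] + 1 and dist[w] <= dist[t]:
                    extend(path + [w])

        extend([s])
        shortest = [p for p in paths if len(p) - 1 == dist[t]]
        if not shortest:
            continue
        for p in shortest:
            for v in p[1:-1]:
                bet[v] += 1.0 / len(shortest)
    return bet


def enumerate_cooccurrence_tails(n: int, na: int, nb: int, k: int) -> tuple[float, float]:
    """P(X >= k) and P(X <= k) for co-presence of two taxa with fixed margins,
    by enumerating all placements of taxon A and counting overlap with a fixed
    placement of taxon B (equivalent to enumerating both by symmetry)."""
    b_set = set(range(nb))
    more = less = total = 0
    for a_set in combinations(range(n), na):
        overlap = len(b_set.intersection(a_set))
        total += 1
        if overlap >= k:
            more += 1
        if overlap <= k:
            less += 1
    return more / total, less / total


def expected_richness_exact(counts: np.ndarray, depth: int) -> float:
    """Expected rarefied richness by exhaustive enumeration over distinct
    subsample compositions (multivariate hypergeometric); tiny inputs only."""
    from math import comb

    counts = [int(c) for c in counts if c > 0]
    n = sum(counts)
    denom = comb(n, depth)

    def rec(i, remaining, picked, ways):
        if i == len(counts):
            if remaining == 0:
                yield picked, ways
            return
        for x in range(0, min(counts[i], remaining) + 1):
            yield from rec(i + 1, remaining - x, picked + (x,), ways * comb(counts[i], x))

    total = 0.0
    for picked, ways in rec(0, depth, (), 1):
        richness = sum(1 for x in picked if x > 0)
        total += richness * ways / denom
    return total
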