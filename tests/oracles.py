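"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from first principles (path enumeration, exact
rational arithmetic, direct rule evaluation) and deliberately shares no code
with the package.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import permutations
from math import comb


def brute_force_betweenness(nodes, pairs) -> dict:
    """Raw betweenness by explicit enumeration of every shortest path.

    For each unordered pair {s, t}, enumerate all shortest s-t paths by
    depth-first search constrained to distance-decreasing steps, then credit
    each interior node with (paths through it) / (total paths).
    """
    nodes = sorted(nodes)
    adj = {v: set() for v in nodes}
    for a, b in pairs:
        adj[a].add(b)
        adj[b].add(a)

    def bfs_dist(src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        return dist

    def all_shortest_paths(s, t, dist_from_t):
        # walk from s toward t, strictly decreasing distance-to-t
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(tuple(path))
                return
            for w in adj[u]:
                if w in dist_from_t and dist_from_t[w] == dist_from_t[u] - 1:
                    extend(path + [w])

        extend([s])
        return paths

    score = {v: Fraction(0) for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            dist_from_t = bfs_dist(t)
            if s not in dist_from_t:
                continue
            paths = all_shortest_paths(s, t, dist_from_t)
            total = len(paths)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                score[v] += Fraction(through, total)
    return {v: float(x) for v, x in score.items()}


def exact_hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return acc


def bh_stepup_rejections(p_values, alpha: float) -> set:
    """Indices rejected by the textbook Benjamini-Hochberg step-up rule."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p_values[idx] <= rank * alpha / m:
            k_star = rank
    return set(order[:k_star])


def brute_force_cycles(arcs: dict, max_len: int = 3) -> set:
    """All simple directed cycles of length 2..max_len, canonical rotation.

    ``arcs`` maps ordered node pairs to an arbitrary payload; returns a set
    of node tuples rotated to start at the smallest node.
    """
    nodes = sorted({u for u, _ in arcs} | {v for _, v in arcs})
    found = set()
    for length in range(2, max_len + 1):
        for combo in permutations(nodes, length):
            if combo[0] != min(combo):
                continue  # canonical rotation only
            closed = all(
                (combo[i], combo[(i + 1) % length]) in arcs for i in range(length)
            )
            if closed:
                found.add(combo)
    return found


def venn_region_sizes(labeled_sets: dict) -> dict:
    """Region sizes by direct membership-vector tally over the union."""
    union = set()
    for genes in labeled_sets.values():
        union |= set(genes)
    regions = {}
    for g in union:
        key = frozenset(l for l, s in labeled_sets.items() if g in s)
        regions[key] = regions.get(key, 0) + 1
    return regions
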