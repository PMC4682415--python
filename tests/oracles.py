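"""Independent brute-force oracles for the test suite.

Everything here is deliberately written from first principles — hand-rolled
BFS with parent-set path reconstruction, exhaustive pair enumeration,
exact integer hypergeometric tail sums — and never calls into the package
under test (nor into networkx path routines), so agreement between the
package and these oracles is a genuine cross-check.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from functools import lru_cache
from itertools import combinations


# ---------------------------------------------------------------------------
# graph primitives


def adjacency(nodes, edges) -> dict:
    adj = {n: set() for n in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def bfs_layers(adj, src):
    """Hop distances and BFS parent sets (all co-minimal predecessors)."""
    dist = {src: 0}
    parents: dict = {src: set()}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parents[v] = {u}
                q.append(v)
            elif dist[v] == dist[u] + 1:
                parents[v].add(u)
    return dist, parents


def enumerate_shortest_paths(adj, src, dst):
    """All distinct shortest paths src -> dst as node tuples."""
    dist, parents = bfs_layers(adj, src)
    if dst not in dist:
        return []
    paths = []

    def walk(node, suffix):
        if node == src:
            paths.append((src, *suffix))
            return
        for p in parents[node]:
            walk(p, (node, *suffix))

    walk(dst, ())
    return paths


# ---------------------------------------------------------------------------
# subnetwork construction oracle (straight from the recruitment definition)


def subnetwork_oracle(nodes, edges, candidates, targets=None):
    """Brute-force node/edge sets for the one- or two-set subnetwork.

    Returns (node_set, edge_set) where edges are sorted 2-tuples: all
    candidate-incident edges plus every edge of every shortest path from
    each candidate to its minimally distant counterpart(s).
    """
    adj = adjacency(nodes, edges)
    candidates = list(candidates)
    cand_set = set(candidates)
    out_nodes = set(cand_set)
    out_edges = set()
    if targets is not None:
        out_nodes |= set(targets)
    for c in candidates:
        for nbr in adj[c]:
            out_nodes.add(nbr)
            out_edges.add(tuple(sorted((c, nbr))))
    for c in candidates:
        dist, _ = bfs_layers(adj, c)
        pool = set(targets) if targets is not None else cand_set
        reach = {n: d for n, d in dist.items() if n in pool and d > 0}
        if not reach:
            continue
        dmin = min(reach.values())
        for other, d in reach.items():
            if d != dmin:
                continue
            for path in enumerate_shortest_paths(adj, c, other):
                out_nodes.update(path)
                out_edges.update(
                    tuple(sorted(p)) for p in zip(path, path[1:])
                )
    return out_nodes, out_edges


# ---------------------------------------------------------------------------
# connectivity oracle


def connectivity_oracle(nodes, edges, candidates, targets=None, sentinel=17):
    """(min_spl, avg_spl, disconnected_candidates, pair_count) by exhaustive
    pairwise BFS with the stated counting rules: each pair once, sentinel
    for missing paths, targets unreachable from every candidate excluded,
    only disconnected candidates counted."""
    adj = adjacency(nodes, edges)
    candidates = list(candidates)
    dists = {c: bfs_layers(adj, c)[0] for c in candidates}
    vals = []
    if targets is None:
        for a, b in combinations(candidates, 2):
            vals.append(dists[a].get(b, sentinel))
        disconnected = sum(
            1
            for c in candidates
            if all(o not in dists[c] for o in candidates if o != c)
        )
    else:
        targets = list(targets)
        kept = [
            t
            for t in targets
            if any(t in dists[c] for c in candidates if c != t)
        ]
        for c in candidates:
            for t in kept:
                if c != t:
                    vals.append(dists[c].get(t, sentinel))
        disconnected = sum(
            1
            for c in candidates
            if all(t not in dists[c] for t in targets if t != c)
        )
    if not vals:
        return float(sentinel), float(sentinel), float(disconnected), 0
    return (
        float(min(vals)),
        sum(vals) / len(vals),
        float(disconnected),
        len(vals),
    )


# ---------------------------------------------------------------------------
# exact hypergeometric upper tail (arbitrary-precision integers)


@lru_cache(maxsize=None)
def _binom_row(n: int) -> tuple[int, ...]:
    row = [1] * (n + 1)
    for k in range(1, n + 1):
        row[k] = row[k - 1] * (n - k + 1) // k
    return tuple(row)


def exact_upper_tail(overlap: int, set_a: int, set_b: int, universe: int) -> Fraction:
    """P(X >= overlap), X ~ Hypergeometric(universe, set_a, set_b), exact."""
    ca = _binom_row(set_b)
    cb = _binom_row(universe - set_b)
    total = _binom_row(universe)[set_a]
    num = 0
    for j in range(overlap, min(set_a, set_b) + 1):
        if set_a - j > universe - set_b:
            continue
        num += ca[j] * cb[set_a - j]
    return Fraction(num, total)
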