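"""Independent reference implementations used only by the test suite.

Each oracle is written against a different algorithmic idea than the library
code it checks (Floyd–Warshall vs BFS, geodesic-count combination vs Brandes
accumulation, path-stem + cycle-cover enumeration vs numeric Krylov rank,
hypergeometric mass summation vs scipy's Fisher routine) so that agreement is
meaningful evidence of correctness.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall

from netclass import DirectedNetwork


def random_digraph(rng: np.random.Generator, n: int, p: float, prefix: str = "n") -> DirectedNetwork:
    """Erdos–Renyi style simple digraph with deterministic node labels."""
    width = len(str(max(n - 1, 1)))
    labels = [f"{prefix}{i:0{width}d}" for i in range(n)]
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    edges = [(labels[i], labels[j]) for i, j in zip(*np.nonzero(mask))]
    return DirectedNetwork(nodes=frozenset(labels), edges=frozenset(edges))


def floyd_warshall_lengths(net: DirectedNetwork) -> tuple[list[str], np.ndarray]:
    """All-pairs unweighted shortest-path lengths via scipy Floyd–Warshall.

    Returns (sorted node order, dense matrix with inf for unreachable and 0
    on the diagonal).
    """
    order = net.node_order()
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    rows = [index[u] for u, v in net.edges]
    cols = [index[v] for u, v in net.edges]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    d = floyd_warshall(adj, directed=True, unweighted=True)
    return order, d


def betweenness_oracle(net: DirectedNetwork) -> dict[str, float]:
    """Unnormalized directed betweenness by geodesic-count combination.

    B(v) = sum over ordered pairs (s, t), s != v != t, of
    sigma(s, v) * sigma(v, t) / sigma(s, t) restricted to pairs where v lies
    on a geodesic (d(s, v) + d(v, t) == d(s, t)).  Geodesic counts come from
    plain BFS wavefront counting, not Brandes' dependency accumulation.
    """
    order = net.node_order()
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in net.edges:
        adj[index[u]].append(index[v])

    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0.0
        sigma[s, s] = 1.0
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if not np.isfinite(dist[s, w]):
                    dist[s, w] = dist[s, u] + 1
                    q.append(w)
                if dist[s, w] == dist[s, u] + 1:
                    sigma[s, w] += sigma[s, u]

    b = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(dist[s, t]):
                continue
            on_path = np.isfinite(dist[s, :]) & np.isfinite(dist[:, t]) \
                & (dist[s, :] + dist[:, t] == dist[s, t])
            on_path[s] = on_path[t] = False
            contrib = np.where(on_path, sigma[s, :] * sigma[:, t], 0.0) / sigma[s, t]
            b += contrib
    return {order[i]: float(b[i]) for i in range(n)}


def control_centrality_oracle(net: DirectedNetwork, node: str) -> int:
    """Generic single-input control centrality by structural enumeration.

    The generic dimension of the controllable subspace from v equals the
    largest vertex set coverable by a "cactus stem + cycles" structure: a
    simple directed path starting at v, plus vertex-disjoint directed cycles
    on reachable vertices not used by the path.  A vertex set admits a
    disjoint cycle cover iff the bipartite graph (out-copies -> in-copies of
    the set, edges restricted to the set) has a perfect matching.  Feasible
    for n <= ~10 only.
    """
    order = net.node_order()
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in net.edges:
        adj[index[u]].append(index[v])
    start = index[node]

    reach = {start}
    q = deque([start])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in reach:
                reach.add(w)
                q.append(w)

    def has_perfect_matching(members: frozenset[int]) -> bool:
        verts = sorted(members)
        pos = {v: i for i, v in enumerate(verts)}
        right = [[pos[w] for w in adj[v] if w in members] for v in verts]
        match_r = [-1] * len(verts)

        def augment(u: int, seen: list[bool]) -> bool:
            for r in right[u]:
                if not seen[r]:
                    seen[r] = True
                    if match_r[r] == -1 or augment(match_r[r], seen):
                        match_r[r] = u
                        return True
            return False

        return all(augment(u, [False] * len(verts)) for u in range(len(verts)))

    cover_cache: dict[frozenset[int], int] = {frozenset(): 0}

    def max_cycle_cover(members: frozenset[int]) -> int:
        if members in cover_cache:
            return cover_cache[members]
        if has_perfect_matching(members):
            best = len(members)
        else:
            best = max(max_cycle_cover(members - {v}) for v in members)
        cover_cache[members] = best
        return best

    best = 0

    def dfs(u: int, visited: frozenset[int]) -> None:
        nonlocal best
        best = max(best, len(visited) + max_cycle_cover(frozenset(reach - visited)))
        for w in adj[u]:
            if w in reach and w not in visited:
                dfs(w, visited | {w})

    dfs(start, frozenset([start]))
    return best


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by summing the hypergeometric mass of all
    tables at most as probable as the observed one (with a tiny relative
    tolerance for float-equal masses)."""
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_total, row1, col1)
    p_obs = pmf[support == a][0]
    return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())


def bh_adjust_oracle(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values from the textbook formula."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
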