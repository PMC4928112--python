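"""Single-input structural control centrality.

The control centrality C_c(v) of node v is the generic dimension of the
subspace of network states that a single input attached to v can steer —
the rank, for almost every choice of edge weights, of the controllability
(Krylov) matrix [b, Ab, A^2 b, ...] where A is the weighted adjacency matrix
(A[j, i] = weight of edge i->j) and b = e_v.  Because the generic rank is
attained with probability 1 for a random weight draw, we assign independent
random weights, compute the numeric Krylov rank by the Arnoldi process
(orthonormalization with breakdown detection), repeat for ``draws`` weight
draws and keep the maximum.

The computation is restricted to the subgraph reachable from v, since the
Krylov vectors are supported there; hence 1 <= C_c(v) <= |reachable(v)|+...
(v counts itself).  C_c is invariant under node relabeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .network import DirectedNetwork, NodeClassMap

__all__ = [
    "control_centrality",
    "control_centrality_table",
    "class_mean_control_centrality",
]

_BREAKDOWN_TOL = 1e-9
_WEIGHT_HIGH = 2 ** 20


def _krylov_rank(a_sub: sparse.csr_matrix, start: int) -> int:
    """Dimension of the Krylov space of ``a_sub`` from unit vector ``start``.

    Arnoldi with full reorthogonalization; stops at breakdown (the Krylov
    space became invariant) or when the space fills the subgraph.
    """
    m = a_sub.shape[0]
    q = np.zeros((m, m))
    q[start, 0] = 1.0
    rank = 1
    x = q[:, 0]
    while rank < m:
        y = a_sub @ x
        scale = np.linalg.norm(y)
        if scale <= 0.0:
            break
        basis = q[:, :rank]
        y = y - basis @ (basis.T @ y)
        y = y - basis @ (basis.T @ y)  # second pass for numerical safety
        resid = np.linalg.norm(y)
        if resid <= _BREAKDOWN_TOL * scale:
            break
        q[:, rank] = y / resid
        x = q[:, rank]
        rank += 1
    return rank


def control_centrality_table(
    net: DirectedNetwork,
    nodes: list[str] | None = None,
    draws: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Control centrality for ``nodes`` (default: every node).

    Returns an integer Series indexed by node identifier.  Deterministic
    given (``draws``, ``seed``).
    """
    g = net.to_igraph()
    order = g.vs["name"]
    index = {v: i for i, v in enumerate(order)}
    if nodes is None:
        nodes = order
    for v in nodes:
        if v not in index:
            raise ValueError(f"node {v!r} not in network")
    n = g.vcount()
    rows, cols = [], []
    for u, w in net.edges:  # A[target, source]
        rows.append(index[w])
        cols.append(index[u])
    rng = np.random.default_rng(seed)
    draw_mats = []
    for _ in range(max(1, draws)):
        weights = rng.integers(1, _WEIGHT_HIGH, size=len(rows)).astype(float)
        draw_mats.append(sparse.csr_matrix((weights, (rows, cols)), shape=(n, n)))

    out: dict[str, int] = {}
    for v in nodes:
        vi = index[v]
        reach = sorted(g.subcomponent(vi, mode="out"))
        pos = reach.index(vi)
        best = 1
        for a in draw_mats:
            a_sub = a[reach][:, reach]
            best = max(best, _krylov_rank(a_sub, pos))
            if best == len(reach):
                break
        out[v] = best
    return pd.Series(out, name="control_centrality", dtype=int)


def control_centrality(net: DirectedNetwork, node: str, draws: int = 3, seed: int = 0) -> int:
    """Control centrality of a single node (see module docstring)."""
    return int(control_centrality_table(net, nodes=[node], draws=draws, seed=seed).iloc[0])


def class_mean_control_centrality(
    results: pd.Series,
    classes: NodeClassMap,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class normalized mean control centrality and pairwise comparisons.

    Normalization divides C_c by the network size n, so a class mean of 1
    would mean every member can steer the entire network.  Returns
    ``(per_class, pairwise)`` where ``pairwise`` holds two-sided rank-sum
    p-values on the normalized values.
    """
    n = classes.universe.n_nodes
    names = classes.names()
    values: dict[str, np.ndarray] = {}
    for cname in names:
        members = sorted(classes[cname])
        if not members:
            raise ValueError(f"class {cname!r} is empty")
        missing = [m for m in members if m not in results.index]
        if missing:
            raise ValueError(f"control centrality missing for {len(missing)} members of {cname!r}")
        values[cname] = results.loc[members].to_numpy(dtype=float) / n
    per_class = pd.DataFrame(
        {
            "n_members": [len(values[c]) for c in names],
            "mean_normalized_cc": [float(values[c].mean()) for c in names],
        },
        index=pd.Index(names, name="class"),
    )
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.all(values[a] == values[a][0]) and np.all(values[b] == values[b][0]) and values[a][0] == values[b][0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(values[a], values[b], alternative="two-sided").pvalue)
            rows.append({"class_a": a, "class_b": b, "p_value": p})
    return per_class, pd.DataFrame(rows)
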