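"""Degree-preserved edge-permutation null model and empirical p-values.

The null model randomizes a digraph by directed double edge swaps
((a->b, c->d) => (a->d, c->b)); swaps that would create a self-loop or a
duplicate edge are rejected, so every node's in- and out-degree — and the
simplicity of the graph — are preserved exactly while higher-order structure
(who reaches whom, and how fast) is destroyed.  This is the null that asks:
is a class-pair statistic explained by degree alone?

For a statistic T, the one-sided empirical p-value over N rewired replicates
is  p = #{T_null >= T_observed} / N  — the plain fraction, which can be 0 at
resolution 1/N; an add-one–smoothed variant (1 + k)/(1 + N) is reported
alongside.  Replicates draw independent sub-seeds derived from the master
seed by counter, so the p-value is invariant to generation order and N can
be extended without recomputing earlier replicates.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Callable

import igraph as ig
import numpy as np

from .geodesics import gr_difference_from_igraph
from .network import DirectedNetwork, NodeClassMap

logger = logging.getLogger(__name__)

__all__ = ["NullDistribution", "rewire_degree_preserved", "permutation_pvalue"]

DEFAULT_N_PERMUTATIONS = 500
DEFAULT_SWAP_MULTIPLIER = 10


@dataclass(frozen=True)
class NullDistribution:
    """Observed statistic, null sample and empirical p-value."""

    statistic: str
    observed: float
    null_values: tuple[float, ...]
    p_value: float
    p_smoothed: float
    n: int
    seed: int
    swap_multiplier: float
    n_undefined: int = 0
    note: str = ""


def _sub_seed(master: int, counter: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence([int(master), int(counter)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _rewire_igraph(g: ig.Graph, swap_multiplier: float, seed: int) -> ig.Graph:
    h = g.copy()
    n_trials = max(1, int(round(swap_multiplier * g.ecount())))
    state = random.getstate()
    try:
        random.seed(seed)  # igraph's default RNG is Python's random module
        h.rewire(n=n_trials)
    finally:
        random.setstate(state)
    return h


def rewire_degree_preserved(
    net: DirectedNetwork,
    swap_multiplier: float = DEFAULT_SWAP_MULTIPLIER,
    seed: int = 0,
) -> DirectedNetwork:
    """One degree-preserved random rewiring of ``net``.

    Attempts ``swap_multiplier * |E|`` directed double edge swaps, rejecting
    any that would create self-loops or duplicate edges.  Deterministic given
    (net, swap_multiplier, seed).  A graph admitting no swap is returned
    unchanged with a warning.
    """
    if net.n_edges < 2:
        logger.warning("network has < 2 edges; rewiring returns it unchanged")
        return net
    g = net.to_igraph()
    h = _rewire_igraph(g, swap_multiplier, seed)
    names = h.vs["name"]
    edges = frozenset((names[u], names[v]) for u, v in h.get_edgelist())
    if edges == net.edges:
        logger.warning("rewiring left the network unchanged (no admissible swaps?)")
    return net.with_edges(edges, name=net.name + "+rewired")


def _statistic_fn(
    statistic: str | Callable[[ig.Graph, list[int], list[int]], float],
) -> Callable[[ig.Graph, list[int], list[int]], float]:
    if callable(statistic):
        return statistic
    if statistic == "gr_diff":
        return gr_difference_from_igraph
    if statistic == "reach_or":

        def _reach_or(g: ig.Graph, first: list[int], second: list[int]) -> float:
            d_fs = np.asarray(g.distances(source=first, target=second, mode="out"))
            d_sf = np.asarray(g.distances(source=second, target=first, mode="out"))
            e_fs = int(np.isfinite(d_fs).sum()); a_fs = d_fs.size - e_fs
            e_sf = int(np.isfinite(d_sf).sum()); a_sf = d_sf.size - e_sf
            if 0 in (e_fs, a_fs, e_sf, a_sf):
                return float("nan")
            return (e_fs / a_fs) / (e_sf / a_sf)

        return _reach_or
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_pvalue(
    net: DirectedNetwork,
    classes: NodeClassMap,
    statistic: str | Callable = "gr_diff",
    ordering: tuple[str, str] = ("first", "second"),
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    swap_multiplier: float = DEFAULT_SWAP_MULTIPLIER,
    seed: int = 0,
) -> NullDistribution:
    """One-sided permutation test of a class-pair statistic.

    The statistic (by default the geodesic-ratio difference D for
    ``ordering = (first_class, second_class)``) is computed on the observed
    network and on ``n_permutations`` degree-preserved rewirings; the
    p-value is the fraction of null values >= the observed one.

    Raises if the statistic is undefined on the observed network or on more
    than 10% of the replicates.
    """
    first_name, second_name = ordering
    u, v = classes[first_name], classes[second_name]
    overlap = u & v
    first_set, second_set = u - overlap, v - overlap
    if not first_set or not second_set:
        raise ValueError("a class is empty after removing the class-pair overlap")
    g = net.to_igraph()
    name_to_idx = {nm: i for i, nm in enumerate(g.vs["name"])}
    first_idx = sorted(name_to_idx[x] for x in first_set)
    second_idx = sorted(name_to_idx[x] for x in second_set)
    fn = _statistic_fn(statistic)
    stat_name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "custom")

    observed = fn(g, first_idx, second_idx)
    if not np.isfinite(observed):
        raise ValueError(f"statistic {stat_name!r} undefined on the observed network")

    null_values: list[float] = []
    n_undefined = 0
    for i in range(n_permutations):
        h = _rewire_igraph(g, swap_multiplier, _sub_seed(seed, i))
        t = fn(h, first_idx, second_idx)
        if np.isfinite(t):
            null_values.append(float(t))
        else:
            n_undefined += 1
    if n_undefined > 0.1 * n_permutations:
        raise ValueError(
            f"statistic {stat_name!r} undefined on {n_undefined}/{n_permutations} "
            f"rewired replicates; null distribution unusable"
        )
    n_eff = len(null_values)
    k = sum(1 for t in null_values if t >= observed)
    p = k / n_eff
    note = ""
    if k == 0:
        note = f"observed exceeds every null value; p < 1/{n_eff} at this resolution"
    return NullDistribution(
        statistic=stat_name,
        observed=float(observed),
        null_values=tuple(null_values),
        p_value=p,
        p_smoothed=(1 + k) / (1 + n_eff),
        n=n_eff,
        seed=seed,
        swap_multiplier=swap_multiplier,
        n_undefined=n_undefined,
        note=note,
    )
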