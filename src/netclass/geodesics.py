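"""Shortest-path machinery: geodesic sets, class-pair reachability, mean
geodesic distributions, nearest-neighbor geodesic vectors and the geodesic
ratio.

All geodesics are unweighted directed shortest paths computed by BFS on the
self-loop-free graph (igraph backend).  Throughout, an ordered class pair
(U, V) is analysed after removing the overlap U∩V from both classes, so
that no pair at distance 0 can enter any statistic.

The geodesic ratio of a class U with respect to a target class V is

    GR_U = mean_u min_v d(u, v)  /  mean_u min_v d(v, u)

— the mean nearest out-geodesic length to V over the mean nearest
in-geodesic length from V.  GR < 1 marks a class that reaches the other
faster than it is reached, i.e. an "upstream" placement.  The test
statistic for a class pair is the difference D = GR_first − GR_second;
D > 0 indicates the first class is more accessible *from* the second
(the first class sits downstream).  Significance comes from the
degree-preserved permutation null in :mod:`netclass.permutation`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .network import DirectedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeodesicSet",
    "ReachabilityResult",
    "NearestGeodesicVectors",
    "GeodesicRatioResult",
    "MeanGeodesicResult",
    "all_geodesics",
    "reachability_fractions",
    "mean_geodesic_distributions",
    "nearest_geodesic_vectors",
    "nearest_geodesic_pair",
    "geodesic_ratio",
    "gr_difference",
    "gr_difference_from_igraph",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class GeodesicSet:
    """Existing/possible geodesic counts and the length multiset for an
    ordered class pair."""

    existing: int
    possible: int
    lengths: tuple[int, ...]

    @property
    def fraction_existing(self) -> float:
        return self.existing / self.possible if self.possible else float("nan")


@dataclass(frozen=True)
class ReachabilityResult:
    """Directional reachability fractions and their odds ratio.

    ``odds_ratio`` is (exist/absent for U->V) / (exist/absent for V->U),
    ``None`` when any cell is zero.
    """

    frac_u_to_v: float
    frac_v_to_u: float
    odds_ratio: float | None
    exist_uv: int
    absent_uv: int
    exist_vu: int
    absent_vu: int


@dataclass(frozen=True)
class NearestGeodesicVectors:
    """Per-node nearest geodesics of class ``source`` toward/from ``target``.

    ``e_out[u]`` is the length of the shortest path from u to any target-class
    node, ``e_in[u]`` the shortest from any target-class node to u; ``None``
    when no path exists.  ``excluded`` are the overlap nodes removed from
    both classes before computation.
    """

    source: str
    target: str
    e_out: dict[str, int | None]
    e_in: dict[str, int | None]
    excluded: frozenset[str]

    def defined_out(self) -> list[int]:
        return [x for x in self.e_out.values() if x is not None]

    def defined_in(self) -> list[int]:
        return [x for x in self.e_in.values() if x is not None]


@dataclass(frozen=True)
class GeodesicRatioResult:
    """Geodesic ratios of an ordered class pair and their difference D."""

    first: str
    second: str
    gr_first: float
    gr_second: float
    d: float
    detail: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class MeanGeodesicResult:
    """Per-node mean geodesics for both class-centric views plus the pooled
    length multisets the rank-sum test runs on."""

    per_node: pd.DataFrame
    pooled_u_to_v: tuple[int, ...]
    pooled_v_to_u: tuple[int, ...]
    ranksum_p: float


# ---------------------------------------------------------------------------
# helpers


def _indices(g: ig.Graph, nodes: frozenset[str] | set[str]) -> list[int]:
    name_to_idx = {v: i for i, v in enumerate(g.vs["name"])}
    return sorted(name_to_idx[v] for v in nodes)


def _dist_matrix(g: ig.Graph, src: list[int], tgt: list[int]) -> np.ndarray:
    return np.asarray(g.distances(source=src, target=tgt, mode="out"), dtype=float)


def _split_overlap(u_set, v_set) -> tuple[frozenset, frozenset, frozenset]:
    u_set, v_set = frozenset(u_set), frozenset(v_set)
    overlap = u_set & v_set
    return u_set - overlap, v_set - overlap, overlap


# ---------------------------------------------------------------------------
# operations


def all_geodesics(net: DirectedNetwork, sources, targets) -> GeodesicSet:
    """All geodesic lengths from ``sources`` to ``targets``.

    Pairs with source == target are excluded from the count of possible
    pairs; unreachable pairs count as possible but not existing.
    """
    sources, targets = frozenset(sources), frozenset(targets)
    if not sources or not targets:
        raise ValueError("sources and targets must be non-empty")
    if not sources <= net.nodes or not targets <= net.nodes:
        raise ValueError("sources/targets must be nodes of the network")
    g = net.to_igraph()
    si, ti = _indices(g, sources), _indices(g, targets)
    d = _dist_matrix(g, si, ti)
    same = np.equal.outer(np.array(si), np.array(ti))
    possible = int((~same).sum())
    finite = np.isfinite(d) & ~same
    lengths = tuple(sorted(int(x) for x in d[finite]))
    return GeodesicSet(existing=len(lengths), possible=possible, lengths=lengths)


def odds_ratio_from_counts(exist_uv: int, absent_uv: int,
                           exist_vu: int, absent_vu: int) -> float | None:
    """Reachability odds ratio (exist/absent)_{U->V} / (exist/absent)_{V->U};
    undefined (None) when any cell is zero."""
    if 0 in (exist_uv, absent_uv, exist_vu, absent_vu):
        return None
    return (exist_uv / absent_uv) / (exist_vu / absent_vu)


def reachability_fractions(net: DirectedNetwork, u_set, v_set) -> ReachabilityResult:
    """Directional reachability fractions between two classes (overlap removed)."""
    u_only, v_only, overlap = _split_overlap(u_set, v_set)
    if not u_only or not v_only:
        raise ValueError("classes identical or empty after removing their overlap")
    fwd = all_geodesics(net, u_only, v_only)
    rev = all_geodesics(net, v_only, u_only)
    e_uv, a_uv = fwd.existing, fwd.possible - fwd.existing
    e_vu, a_vu = rev.existing, rev.possible - rev.existing
    odds = odds_ratio_from_counts(e_uv, a_uv, e_vu, a_vu)
    return ReachabilityResult(
        frac_u_to_v=fwd.fraction_existing,
        frac_v_to_u=rev.fraction_existing,
        odds_ratio=odds,
        exist_uv=e_uv, absent_uv=a_uv, exist_vu=e_vu, absent_vu=a_vu,
    )


def mean_geodesic_distributions(net: DirectedNetwork, u_set, v_set,
                                u_name: str = "U", v_name: str = "V") -> MeanGeodesicResult:
    """Per-node mean out/in geodesics for both class-centric views.

    For each u (class U view): mean length over existing geodesics u->V
    (``mean_out``) and V->u (``mean_in``); symmetrically for each v.  The
    rank-sum p-value compares the *pooled* per-pair length multisets
    U->V vs V->U (all geodesics prior to taking the mean), not the per-node
    means.
    """
    u_only, v_only, _ = _split_overlap(u_set, v_set)
    if not u_only or not v_only:
        raise ValueError("classes identical or empty after removing their overlap")
    g = net.to_igraph()
    ui, vi = _indices(g, u_only), _indices(g, v_only)
    names = g.vs["name"]
    d_uv = _dist_matrix(g, ui, vi)  # rows: u, cols: v
    d_vu = _dist_matrix(g, vi, ui)  # rows: v, cols: u

    def _row_means(mat: np.ndarray) -> np.ndarray:
        finite = np.isfinite(mat)
        counts = finite.sum(axis=1)
        sums = np.where(finite, mat, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / counts, np.nan)

    rows = []
    u_out, u_in = _row_means(d_uv), _row_means(d_vu.T)
    for k, i in enumerate(ui):
        rows.append({"node": names[i], "view": u_name, "mean_out": u_out[k], "mean_in": u_in[k]})
    v_out, v_in = _row_means(d_vu), _row_means(d_uv.T)
    for k, i in enumerate(vi):
        rows.append({"node": names[i], "view": v_name, "mean_out": v_out[k], "mean_in": v_in[k]})

    pooled_uv = tuple(sorted(int(x) for x in d_uv[np.isfinite(d_uv)]))
    pooled_vu = tuple(sorted(int(x) for x in d_vu[np.isfinite(d_vu)]))
    if pooled_uv and pooled_vu:
        if pooled_uv == pooled_vu:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(pooled_uv, pooled_vu, alternative="two-sided").pvalue)
    else:
        p = float("nan")
    return MeanGeodesicResult(
        per_node=pd.DataFrame(rows).set_index(["view", "node"]),
        pooled_u_to_v=pooled_uv,
        pooled_v_to_u=pooled_vu,
        ranksum_p=p,
    )


def nearest_geodesic_pair(
    net: DirectedNetwork, u_set, v_set, u_name: str = "U", v_name: str = "V",
) -> tuple[NearestGeodesicVectors, NearestGeodesicVectors]:
    """Nearest-geodesic vectors for both classes of an ordered pair.

    The overlap U∩V is removed from both classes first so that no length-0
    geodesic between overlapping classes can enter the means.
    """
    u_only, v_only, overlap = _split_overlap(u_set, v_set)
    if not u_only:
        raise ValueError(f"class {u_name!r} empty after removing the {len(overlap)}-node overlap")
    if not v_only:
        raise ValueError(f"class {v_name!r} empty after removing the {len(overlap)}-node overlap")
    g = net.to_igraph()
    ui, vi = _indices(g, u_only), _indices(g, v_only)
    names = g.vs["name"]
    d_uv = _dist_matrix(g, ui, vi)
    d_vu = _dist_matrix(g, vi, ui)

    # distances are +inf for unreachable pairs, so plain min/argmin work
    u_eout, u_ein = d_uv.min(axis=1), d_vu.min(axis=0)
    v_eout, v_ein = d_vu.min(axis=1), d_uv.min(axis=0)

    def _vec(idx, eout, ein, src, tgt):
        e_out = {names[i]: (int(x) if math.isfinite(x) else None) for i, x in zip(idx, eout)}
        e_in = {names[i]: (int(x) if math.isfinite(x) else None) for i, x in zip(idx, ein)}
        n_absent = sum(v is None for v in e_out.values()) + sum(v is None for v in e_in.values())
        if n_absent:
            logger.info("%s vs %s: %d absent nearest-geodesic entries dropped from means", src, tgt, n_absent)
        return NearestGeodesicVectors(source=src, target=tgt, e_out=e_out, e_in=e_in,
                                      excluded=frozenset(overlap))

    return (_vec(ui, u_eout, u_ein, u_name, v_name), _vec(vi, v_eout, v_ein, v_name, u_name))


def nearest_geodesic_vectors(net: DirectedNetwork, u_set, v_set,
                             u_name: str = "U", v_name: str = "V") -> NearestGeodesicVectors:
    """Nearest-geodesic vectors of class U with respect to target class V."""
    return nearest_geodesic_pair(net, u_set, v_set, u_name, v_name)[0]


def geodesic_ratio(
    vec_first: NearestGeodesicVectors,
    vec_second: NearestGeodesicVectors,
) -> GeodesicRatioResult:
    """Geodesic ratios of both classes and their difference D.

    GR = mean(defined nearest out-geodesics) / mean(defined nearest
    in-geodesics); D = GR_first − GR_second.  Swapping the two vectors flips
    the sign of D exactly.
    """
    def _gr(vec: NearestGeodesicVectors) -> tuple[float, dict]:
        eo, ei = vec.defined_out(), vec.defined_in()
        if not eo or not ei:
            raise ValueError(f"class {vec.source!r}: no defined nearest geodesics "
                             f"({'out' if not eo else 'in'} vector all absent)")
        mo, mi = float(np.mean(eo)), float(np.mean(ei))
        return mo / mi, {"mean_out": mo, "mean_in": mi, "n_out": len(eo), "n_in": len(ei),
                         "n_members": len(vec.e_out)}

    gr1, det1 = _gr(vec_first)
    gr2, det2 = _gr(vec_second)
    return GeodesicRatioResult(
        first=vec_first.source, second=vec_second.source,
        gr_first=gr1, gr_second=gr2, d=gr1 - gr2,
        detail={vec_first.source: det1, vec_second.source: det2},
    )


def gr_difference(net: DirectedNetwork, first_set, second_set,
                  first_name: str = "first", second_name: str = "second") -> GeodesicRatioResult:
    """Convenience: nearest-geodesic vectors + geodesic-ratio difference in one call."""
    v1, v2 = nearest_geodesic_pair(net, first_set, second_set, first_name, second_name)
    return geodesic_ratio(v1, v2)


def gr_difference_from_igraph(g: ig.Graph, first_idx: list[int], second_idx: list[int]) -> float:
    """Fast path for the permutation null: D on a pre-indexed igraph graph.

    ``first_idx`` and ``second_idx`` must already be overlap-free.  Returns
    ``nan`` when either class has an all-absent out or in vector.
    """
    d_fs = np.asarray(g.distances(source=first_idx, target=second_idx, mode="out"), dtype=float)
    d_sf = np.asarray(g.distances(source=second_idx, target=first_idx, mode="out"), dtype=float)

    def _gr(out_mat: np.ndarray, in_mat: np.ndarray) -> float:
        eo, ei = out_mat.min(axis=1), in_mat.min(axis=0)
        eo, ei = eo[np.isfinite(eo)], ei[np.isfinite(ei)]
        if len(eo) == 0 or len(ei) == 0:
            return float("nan")
        return float(eo.mean() / ei.mean())

    gr_first = _gr(d_fs, d_sf)
    gr_second = _gr(d_sf, d_fs)
    return gr_first - gr_second
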