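"""Degree, closeness and betweenness centralities; power-law fits; class comparisons.

All distances are unweighted directed geodesics (BFS) on the self-loop-free
graph.  Betweenness is Brandes' exact algorithm (igraph backend), endpoints
excluded, unnormalized.  Out-closeness of a node v is

    C(v) = 1 / sum_x d(v, x)

with the sum over nodes reachable from v; a node reaching nothing gets 0.
Because real interactomes are not strongly connected, a normalized variant
(Wasserman–Faust) is also reported:

    C_norm(v) = (R_v / sum_x d(v, x)) * (R_v / (n - 1))

where R_v is the number of nodes reachable from v (excluding v).  C_norm is
in [0, 1] and equals 1 on a complete digraph; it is the default metric for
class comparisons of closeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import DirectedNetwork, NodeClassMap

__all__ = [
    "compute_degrees",
    "compute_closeness_out",
    "compute_betweenness",
    "centrality_table",
    "PowerLawFit",
    "fit_power_law",
    "fit_log_frequencies",
    "ClassComparison",
    "compare_class_centrality",
]


def compute_degrees(net: DirectedNetwork) -> pd.DataFrame:
    """Exact in/out degree per node, indexed by node identifier."""
    if not net.nodes:
        raise ValueError("network is empty")
    g = net.to_igraph()
    return pd.DataFrame(
        {"out_degree": g.outdegree(), "in_degree": g.indegree()},
        index=pd.Index(g.vs["name"], name="node"),
    )


def compute_closeness_out(net: DirectedNetwork) -> pd.DataFrame:
    """Raw and normalized out-closeness per node (see module docstring)."""
    g = net.to_igraph()
    n = g.vcount()
    d = np.asarray(g.distances(mode="out"), dtype=float)
    np.fill_diagonal(d, np.inf)
    reachable = np.isfinite(d)
    r = reachable.sum(axis=1).astype(float)
    total = np.where(reachable, d, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(total > 0, 1.0 / total, 0.0)
        norm = np.where(total > 0, (r / total) * (r / max(n - 1, 1)), 0.0)
    return pd.DataFrame(
        {"closeness_out_raw": raw, "closeness_out": norm},
        index=pd.Index(g.vs["name"], name="node"),
    )


def compute_betweenness(net: DirectedNetwork) -> pd.DataFrame:
    """Unnormalized directed betweenness B(v) = sum_{i!=v!=j} g_ivj / g_ij."""
    g = net.to_igraph()
    return pd.DataFrame(
        {"betweenness": g.betweenness(directed=True)},
        index=pd.Index(g.vs["name"], name="node"),
    )


def centrality_table(net: DirectedNetwork) -> pd.DataFrame:
    """Degrees, closeness and betweenness in one table (control centrality is
    filled in separately by :mod:`netclass.control`)."""
    parts = [compute_degrees(net), compute_closeness_out(net), compute_betweenness(net)]
    return pd.concat(parts, axis=1)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log degree frequency on log degree.

    ``gamma`` is minus the slope (the degree exponent); ``r_squared`` the
    coefficient of determination of the log-log regression.
    """

    gamma: float
    r_squared: float
    intercept: float
    side: str
    n_points: int


def fit_log_frequencies(degrees: Sequence[float], freqs: Sequence[float], side: str = "out") -> PowerLawFit:
    """Fit log(freq) ~ log(degree) by ordinary least squares.

    Accepts unrounded frequencies; zero degrees or non-positive frequencies
    are invalid here (callers filter them).  Requires >= 3 points.
    """
    k = np.asarray(degrees, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if len(k) < 3:
        raise ValueError("power-law fit needs >= 3 distinct positive degrees")
    if np.any(k <= 0) or np.any(f <= 0):
        raise ValueError("degrees and frequencies must be positive")
    res = stats.linregress(np.log(k), np.log(f))
    return PowerLawFit(
        gamma=-float(res.slope),
        r_squared=float(res.rvalue) ** 2,
        intercept=float(res.intercept),
        side=side,
        n_points=len(k),
    )


def fit_power_law(degrees: Sequence[int], side: str = "out") -> PowerLawFit:
    """Fit the degree exponent from a raw degree sequence.

    Distinct positive degrees and their observed frequencies enter the
    log-log OLS directly (no binning); zero degrees are excluded.
    """
    arr = np.asarray(degrees, dtype=int)
    arr = arr[arr > 0]
    k, f = np.unique(arr, return_counts=True)
    if len(k) < 3:
        raise ValueError("power-law fit needs >= 3 distinct positive degrees")
    return fit_log_frequencies(k, f, side=side)


@dataclass(frozen=True)
class ClassComparison:
    """Two-sided rank-sum comparison of a centrality metric between groups."""

    class_a: str
    class_b: str
    metric: str
    p_value: float
    direction: str | None  # class whose median is larger, None on a tie
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def compare_class_centrality(
    table: pd.DataFrame,
    classes: NodeClassMap,
    metric: str,
    a: str,
    b: str = "all",
) -> ClassComparison:
    """Mann–Whitney (Wilcoxon rank-sum) test of ``metric`` between two groups.

    ``b="all"`` compares class ``a`` against every node of the network.
    Two-sided by convention; direction reports the group with the larger
    median.
    """
    if metric not in table.columns:
        raise ValueError(f"metric {metric!r} not in table columns {list(table.columns)}")
    va = table.loc[sorted(classes[a]), metric].to_numpy(dtype=float)
    if b == "all":
        vb = table[metric].to_numpy(dtype=float)
    else:
        vb = table.loc[sorted(classes[b]), metric].to_numpy(dtype=float)
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("both comparison groups must be non-empty")
    p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
    ma, mb = float(np.median(va)), float(np.median(vb))
    direction = None if ma == mb else (a if ma > mb else b)
    return ClassComparison(
        class_a=a, class_b=b, metric=metric, p_value=p,
        direction=direction, median_a=ma, median_b=mb, n_a=len(va), n_b=len(vb),
    )
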