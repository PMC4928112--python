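"""Three-layer hierarchy stratification and Fisher-exact enrichment.

Stratification assigns every node to one of three layers — top, middle,
bottom — by maximizing the *hierarchy score*, the fraction of edges that
point strictly downward (from a higher to a lower layer).  The optimizer is
seeded simulated annealing restarted from many random labelings; a node's
layer-membership probability is the fraction of restarts that place it in
that layer (after aligning layer order across restarts), and a hard label
is assigned only when that probability exceeds 0.5.  This is an "HSM-like"
stratifier: it reproduces the output contract of hierarchical-score
maximization (three layers, per-node probabilities, >0.5 assignment) with a
documented in-package objective.

Enrichment of a node class in a layer (or any annotation set) uses the
two-sided Fisher exact test on the 2x2 membership table over the network
universe, with fold enrichment = (overlap/|class|) / (|target|/|universe|)
and optional Benjamini–Hochberg adjustment across annotation sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import AnnotationSets, DirectedNetwork, NodeClassMap

logger = logging.getLogger(__name__)

__all__ = [
    "HierarchyAssignment",
    "stratify_hierarchy",
    "hierarchy_score",
    "EnrichmentResult",
    "fisher_enrichment",
    "layer_enrichment",
    "class_overlap_analysis",
    "annotation_enrichment",
]

LAYERS = ("top", "middle", "bottom")


@dataclass(frozen=True)
class HierarchyAssignment:
    """Per-node layer probabilities, hard labels and optimizer metadata.

    ``table`` has columns p_top, p_middle, p_bottom (summing to 1) and
    ``layer`` in {top, middle, bottom, unassigned}; ``metadata`` records
    restarts, seed, per-restart initial/best scores and the best score found.
    """

    table: pd.DataFrame
    metadata: dict = field(compare=False)

    def layer_nodes(self, layer: str) -> frozenset[str]:
        return frozenset(self.table.index[self.table["layer"] == layer])


def hierarchy_score(labels: np.ndarray, src: np.ndarray, dst: np.ndarray) -> float:
    """Fraction of edges pointing strictly downward under a 0/1/2 labeling."""
    if len(src) == 0:
        return 1.0
    return float((labels[src] < labels[dst]).sum() / len(src))


def _anneal_once(
    src: np.ndarray,
    dst: np.ndarray,
    in_nbrs: list[np.ndarray],
    out_nbrs: list[np.ndarray],
    n: int,
    rng: np.random.Generator,
    steps: int,
) -> tuple[np.ndarray, float, float]:
    """One annealing restart; returns (best labels, init score, best score)."""
    labels = rng.integers(0, 3, size=n)
    n_edges = max(len(src), 1)
    down = int((labels[src] < labels[dst]).sum())
    init_score = down / n_edges if len(src) else 1.0
    best_down, best_labels = down, labels.copy()

    t0, t1 = 1.5, 0.02
    cool = (t1 / t0) ** (1.0 / max(steps - 1, 1))
    temp = t0
    nodes = rng.integers(0, n, size=steps)
    props = rng.integers(0, 3, size=steps)
    accept_u = rng.random(size=steps)
    for v, new, u in zip(nodes, props, accept_u):
        old = labels[v]
        if new != old:
            inn, out = in_nbrs[v], out_nbrs[v]
            delta = (
                int((labels[inn] < new).sum()) - int((labels[inn] < old).sum())
                + int((new < labels[out]).sum()) - int((old < labels[out]).sum())
            )
            if delta >= 0 or u < np.exp(delta / temp):
                labels[v] = new
                down += delta
                if down > best_down:
                    best_down, best_labels = down, labels.copy()
        temp *= cool
    best_score = best_down / n_edges if len(src) else 1.0
    return best_labels, init_score, best_score


def _align_layers(labels: np.ndarray, depth_rank: np.ndarray) -> np.ndarray:
    """Canonical layer order: ascending mean depth statistic, ties broken by
    larger layers first (keeps degenerate edgeless graphs deterministic)."""
    keys = []
    for layer in range(3):
        mask = labels == layer
        mean_r = float(depth_rank[mask].mean()) if mask.any() else 0.0
        keys.append((mean_r, -int(mask.sum()), layer))
    order = [layer for _, _, layer in sorted(keys)]
    remap = np.empty(3, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return remap[labels]


def stratify_hierarchy(
    net: DirectedNetwork,
    restarts: int = 50,
    seed: int = 0,
    steps_per_node: int = 60,
) -> HierarchyAssignment:
    """Stratify a network into top/middle/bottom layers (see module docstring).

    ``restarts`` must be >= 3 for the restart-frequency probabilities to be
    meaningful.  Deterministic given (restarts, seed, steps_per_node).
    """
    if restarts < 3:
        raise ValueError("need >= 3 restarts for meaningful layer probabilities")
    order = net.node_order()
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    src = np.fromiter((index[u] for u, v in sorted(net.edges)), dtype=int, count=net.n_edges)
    dst = np.fromiter((index[v] for u, v in sorted(net.edges)), dtype=int, count=net.n_edges)
    in_nbrs = [np.array([], dtype=int) for _ in range(n)]
    out_nbrs = [np.array([], dtype=int) for _ in range(n)]
    tmp_in: list[list[int]] = [[] for _ in range(n)]
    tmp_out: list[list[int]] = [[] for _ in range(n)]
    for s, d in zip(src, dst):
        tmp_out[s].append(d)
        tmp_in[d].append(s)
    for v in range(n):
        in_nbrs[v] = np.array(tmp_in[v], dtype=int)
        out_nbrs[v] = np.array(tmp_out[v], dtype=int)

    # depth statistic for cross-restart alignment: sinks (in >> out) are deep
    depth_rank = np.array([len(tmp_in[v]) - len(tmp_out[v]) for v in range(n)], dtype=float)

    steps = max(steps_per_node * n, 200)
    counts = np.zeros((n, 3), dtype=float)
    scores = []
    best_overall = -1.0
    rng_master = np.random.SeedSequence([int(seed), 2])
    for child in rng_master.spawn(restarts):
        rng = np.random.default_rng(child)
        labels, init_score, best_score = _anneal_once(src, dst, in_nbrs, out_nbrs, n, rng, steps)
        labels = _align_layers(labels, depth_rank)
        counts[np.arange(n), labels] += 1.0
        scores.append({"init_score": init_score, "best_score": best_score})
        best_overall = max(best_overall, best_score)

    probs = counts / restarts
    hard = np.full(n, "unassigned", dtype=object)
    winner = probs.argmax(axis=1)
    assigned = probs[np.arange(n), winner] > 0.5
    hard[assigned] = np.array(LAYERS, dtype=object)[winner[assigned]]
    table = pd.DataFrame(
        {"p_top": probs[:, 0], "p_middle": probs[:, 1], "p_bottom": probs[:, 2], "layer": hard},
        index=pd.Index(order, name="node"),
    )
    return HierarchyAssignment(
        table=table,
        metadata={"restarts": restarts, "seed": seed, "steps_per_node": steps_per_node,
                  "best_score": best_overall, "restart_scores": scores},
    )


# ---------------------------------------------------------------------------
# Fisher enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 Fisher enrichment of a member set in a target set over a universe.

    Table cells: a = |members∩target|, b = |members\\target|,
    c = |target\\members|, d = rest of the universe.
    """

    members_name: str
    target_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float  # inf when b*c == 0 and a*d > 0
    fold: float
    p_value: float
    p_adjusted: float | None = None


def fisher_enrichment(
    members: frozenset[str] | set[str],
    target: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    members_name: str = "members",
    target_name: str = "target",
) -> EnrichmentResult:
    """Two-sided Fisher exact enrichment of ``members`` in ``target``.

    Fold enrichment is the observed overlap proportion over the expected
    proportion under independence.  Raises on an empty universe or empty
    member/target sets (fold would be undefined).
    """
    members, target, universe = frozenset(members), frozenset(target), frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    if not members <= universe or not target <= universe:
        raise ValueError("members and target must be subsets of the universe")
    if not members or not target:
        raise ValueError("members and target must be non-empty")
    a = len(members & target)
    b = len(members) - a
    c = len(target) - a
    d = len(universe) - a - b - c
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    fold = (a / len(members)) / (len(target) / len(universe))
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return EnrichmentResult(members_name, target_name, a, b, c, d, odds, fold, p)


def layer_enrichment(classes: NodeClassMap, assignment: HierarchyAssignment) -> pd.DataFrame:
    """Fisher enrichment of every class in every hierarchy layer.

    The universe is the full node set; layer enrichments (3 tests per class)
    are reported unadjusted, matching how layer-wise enrichment is usually
    plotted against an odds-ratio reference line of 1.
    """
    universe = classes.universe.nodes
    rows = []
    for cname in classes.names():
        for layer in LAYERS:
            target = assignment.layer_nodes(layer)
            if not target:
                logger.warning("layer %r is empty; skipping enrichment", layer)
                continue
            r = fisher_enrichment(classes[cname], target, universe, cname, layer)
            rows.append({"class": cname, "layer": layer, "overlap": r.a,
                         "class_size": r.a + r.b, "layer_size": r.a + r.c,
                         "odds_ratio": r.odds_ratio, "fold": r.fold, "p_value": r.p_value})
    return pd.DataFrame(rows)


def class_overlap_analysis(classes: NodeClassMap) -> tuple[pd.DataFrame, int]:
    """Pairwise class overlaps with Fisher enrichment over the network.

    Returns the pairwise table and the size of the all-classes intersection
    (for Venn-style reporting).
    """
    names = classes.names()
    if len(names) < 2:
        raise ValueError("need at least 2 classes")
    universe = classes.universe.nodes
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = fisher_enrichment(classes[a], classes[b], universe, a, b)
            rows.append({"class_a": a, "class_b": b, "overlap": r.a,
                         "size_a": len(classes[a]), "size_b": len(classes[b]),
                         "odds_ratio": r.odds_ratio, "fold": r.fold, "p_value": r.p_value})
    triple = len(frozenset.intersection(*(classes[c] for c in names)))
    return pd.DataFrame(rows), triple


def annotation_enrichment(
    classes: NodeClassMap,
    sets: AnnotationSets,
    correction: str = "BH",
) -> pd.DataFrame:
    """Fisher enrichment of every class in every annotation set.

    Annotation members absent from the network universe are dropped with a
    logged count; sets empty after restriction are skipped.  ``correction``
    is ``"BH"`` (Benjamini–Hochberg across sets within each class) or
    ``"none"``.
    """
    if correction not in ("BH", "none"):
        raise ValueError("correction must be 'BH' or 'none'")
    if not sets.sets:
        raise ValueError("annotation sets are empty")
    universe = classes.universe.nodes
    restricted: dict[str, frozenset[str]] = {}
    for sname in sets.names():
        inside = sets[sname] & universe
        dropped = len(sets[sname]) - len(inside)
        if dropped:
            logger.info("annotation set %r: %d members outside the network dropped", sname, dropped)
        if inside:
            restricted[sname] = inside
        else:
            logger.warning("annotation set %r empty after restriction; skipped", sname)

    frames = []
    for cname in classes.names():
        rows = []
        for sname, target in restricted.items():
            r = fisher_enrichment(classes[cname], target, universe, cname, sname)
            rows.append({"class": cname, "set": sname, "overlap": r.a,
                         "set_size": len(target), "odds_ratio": r.odds_ratio,
                         "fold": r.fold, "p_value": r.p_value})
        df = pd.DataFrame(rows)
        if correction == "BH" and len(df):
            df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        else:
            df["p_adjusted"] = df["p_value"] if len(df) else []
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
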