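"""End-to-end orchestration: load/simulate -> overlaps -> centralities ->
scale-free fits -> geodesics -> permutation tests -> hierarchy -> enrichment.

One :class:`AnalysisConfig` drives the whole workflow; :func:`run_pipeline`
returns an :class:`AnalysisReport` whose JSON body (plus TSV sidecar tables)
fully reproduces under the same config and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_table, compare_class_centrality, fit_power_law
from .control import class_mean_control_centrality, control_centrality_table
from .geodesics import gr_difference, mean_geodesic_distributions, reachability_fractions
from .hierarchy import annotation_enrichment, class_overlap_analysis, layer_enrichment, stratify_hierarchy
from .io import build_class_map, load_edge_list, load_gmt, write_edge_list
from .network import DirectedNetwork, NodeClassMap
from .permutation import permutation_pvalue
from .synthetic import SyntheticSpec, generate_study_network

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline", "render_summary"]


@dataclass
class AnalysisConfig:
    """Inputs and parameters of one full analysis run.

    Exactly one of ``edges_path`` or ``synthetic`` must be given.  The
    ``orderings`` list names the class pairs to test; per the test-statistic
    convention, put the candidate *downstream* class first (D > 0 then means
    "first class is more accessible from the second").
    """

    edges_path: str | None = None
    class_files: Mapping[str, str] = field(default_factory=dict)
    synthetic: SyntheticSpec | None = None
    gmt_path: str | None = None
    orderings: list[tuple[str, str]] = field(default_factory=list)
    n_permutations: int = 500
    swap_multiplier: float = 10.0
    restarts: int = 50
    control_nodes: str = "classes"  # "classes" | "all" | "none"
    control_draws: int = 2
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.edges_path is None) == (self.synthetic is None):
            raise ValueError("give exactly one of edges_path or synthetic")
        if self.control_nodes not in ("classes", "all", "none"):
            raise ValueError("control_nodes must be 'classes', 'all' or 'none'")
        if self.edges_path is not None:
            for p in [self.edges_path, *self.class_files.values()] + ([self.gmt_path] if self.gmt_path else []):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        self.orderings = [tuple(o) for o in self.orderings]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "overlap_sizes" in syn:
                syn["overlap_sizes"] = {tuple(k.split("|")): v for k, v in syn["overlap_sizes"].items()}
            raw["synthetic"] = SyntheticSpec(**syn)
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Structured results of every pipeline stage plus provenance."""

    blocks: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.blocks[key]

    def __contains__(self, key: str) -> bool:
        return key in self.blocks

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.blocks, indent=indent, default=_jsonable)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _jsonable(x: Any) -> Any:
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, tuple, set, frozenset)):
        return list(x)
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return dataclasses.asdict(x)
    if isinstance(x, pd.DataFrame):
        return x.reset_index().to_dict(orient="records")
    if isinstance(x, pd.Series):
        return x.to_dict()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _load_inputs(config: AnalysisConfig) -> tuple[DirectedNetwork, NodeClassMap]:
    if config.synthetic is not None:
        return generate_study_network(config.synthetic)
    net = load_edge_list(config.edges_path)
    classes = build_class_map(net, config.class_files)
    return net, classes


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute every stage in dependency order and return the report.

    Stage failures raise with the stage name; with ``config.out_dir`` set,
    TSV sidecars for every table and the JSON report are written there.
    """
    t_start = time.time()
    blocks: dict[str, Any] = {"config": _config_snapshot(config), "versions": {"netclass": __version__}}
    runtimes: dict[str, float] = {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            runtimes[name] = round(time.time() - t0, 3)
        return deco

    state: dict[str, Any] = {}

    @_stage("load")
    def _():
        net, classes = _load_inputs(config)
        state["net"], state["classes"] = net, classes
        blocks["network"] = {"name": net.name, "n_nodes": net.n_nodes, "n_edges": net.n_edges,
                             "class_sizes": {c: len(classes[c]) for c in classes.names()}}
        if out_dir:
            write_edge_list(net, out_dir / "edges.tsv")
            for c in classes.names():
                (out_dir / f"class_{c}.txt").write_text("\n".join(sorted(classes[c])) + "\n")

    net: DirectedNetwork = state["net"]
    classes: NodeClassMap = state["classes"]
    pair_names = config.orderings or _default_orderings(classes)

    @_stage("overlaps")
    def _():
        table, triple = class_overlap_analysis(classes)
        blocks["overlaps"] = {"pairwise": table, "triple_overlap": triple}
        if out_dir:
            table.to_csv(out_dir / "overlaps.tsv", sep="\t", index=False)

    @_stage("centrality")
    def _():
        table = centrality_table(net)
        state["centrality"] = table
        fits = {}
        for side, col in (("out", "out_degree"), ("in", "in_degree")):
            try:
                f = fit_power_law(table[col].to_numpy(), side=side)
                fits[side] = {"gamma": f.gamma, "r_squared": f.r_squared, "n_points": f.n_points}
            except ValueError as exc:
                fits[side] = {"error": str(exc)}
        comparisons = []
        names = classes.names()
        for metric in ("out_degree", "in_degree", "closeness_out", "betweenness"):
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    c = compare_class_centrality(table, classes, metric, a, b)
                    comparisons.append({"metric": metric, "class_a": a, "class_b": b,
                                        "p_value": c.p_value, "direction": c.direction,
                                        "median_a": c.median_a, "median_b": c.median_b})
        blocks["power_law"] = fits
        blocks["centrality_comparisons"] = comparisons
        if out_dir:
            table.to_csv(out_dir / "centrality.tsv", sep="\t")

    @_stage("control")
    def _():
        if config.control_nodes == "none":
            blocks["control"] = {"skipped": True}
            return
        if config.control_nodes == "all":
            nodes = None
        else:
            nodes = sorted(set().union(*(classes[c] for c in classes.names())))
        cc = control_centrality_table(net, nodes=nodes, draws=config.control_draws, seed=config.seed)
        per_class, pairwise = class_mean_control_centrality(cc, classes)
        blocks["control"] = {"per_class": per_class, "pairwise": pairwise,
                             "draws": config.control_draws, "seed": config.seed}
        if out_dir:
            cc.to_csv(out_dir / "control_centrality.tsv", sep="\t", header=True)
        if config.control_nodes == "all":
            state.setdefault("centrality", pd.DataFrame())
            state["centrality"]["control_centrality"] = cc

    @_stage("geodesics")
    def _():
        geo = {}
        for first, second in pair_names:
            reach = reachability_fractions(net, classes[first], classes[second])
            means = mean_geodesic_distributions(net, classes[first], classes[second], first, second)
            gr = gr_difference(net, classes[first], classes[second], first, second)
            key = f"{first}_vs_{second}"
            geo[key] = {
                "reachability": reach,
                "mean_geodesics_ranksum_p": means.ranksum_p,
                "gr_first": gr.gr_first, "gr_second": gr.gr_second, "d": gr.d,
                "detail": gr.detail,
            }
            if out_dir:
                means.per_node.to_csv(out_dir / f"mean_geodesics_{key}.tsv", sep="\t")
        blocks["geodesics"] = geo

    @_stage("permutation")
    def _():
        perm = {}
        for first, second in pair_names:
            nd = permutation_pvalue(
                net, classes, statistic="gr_diff", ordering=(first, second),
                n_permutations=config.n_permutations,
                swap_multiplier=config.swap_multiplier, seed=config.seed,
            )
            key = f"{first}_vs_{second}"
            perm[key] = {"statistic": nd.statistic, "observed": nd.observed,
                         "p_value": nd.p_value, "p_smoothed": nd.p_smoothed,
                         "n": nd.n, "n_undefined": nd.n_undefined, "note": nd.note}
            if out_dir:
                pd.Series(nd.null_values, name="gr_diff_null").to_csv(
                    out_dir / f"null_{key}.tsv", sep="\t", index=False)
        blocks["permutation"] = perm

    @_stage("hierarchy")
    def _():
        assign = stratify_hierarchy(net, restarts=config.restarts, seed=config.seed)
        enr = layer_enrichment(classes, assign)
        counts = assign.table["layer"].value_counts().to_dict()
        blocks["hierarchy"] = {"layer_counts": counts,
                               "best_score": assign.metadata["best_score"],
                               "restarts": config.restarts,
                               "layer_enrichment": enr}
        if out_dir:
            assign.table.to_csv(out_dir / "hierarchy.tsv", sep="\t")
            enr.to_csv(out_dir / "layer_enrichment.tsv", sep="\t", index=False)

    @_stage("annotation")
    def _():
        if not config.gmt_path:
            blocks["annotation"] = {"skipped": True}
            return
        sets = load_gmt(config.gmt_path)
        enr = annotation_enrichment(classes, sets)
        blocks["annotation"] = {"table": enr}
        if out_dir:
            enr.to_csv(out_dir / "annotation_enrichment.tsv", sep="\t", index=False)

    blocks["runtimes"] = runtimes
    blocks["total_runtime"] = round(time.time() - t_start, 3)
    report = AnalysisReport(blocks=blocks)
    if out_dir:
        report.write(out_dir / "report.json")
        (out_dir / "summary.md").write_text(render_summary(report))
    return report


def _default_orderings(classes: NodeClassMap) -> list[tuple[str, str]]:
    """Pair every later class (candidate downstream) with every earlier one."""
    names = classes.names()
    return [(b, a) for i, a in enumerate(names) for b in names[i + 1:]]


def _config_snapshot(config: AnalysisConfig) -> dict:
    snap = dataclasses.asdict(config)
    if config.synthetic is not None:
        syn = dataclasses.asdict(config.synthetic)
        syn["overlap_sizes"] = {"|".join(k): v for k, v in config.synthetic.overlap_sizes.items()}
        syn["class_sizes"] = dict(config.synthetic.class_sizes)
        snap["synthetic"] = syn
    snap["orderings"] = [list(o) for o in config.orderings]
    return snap


def render_summary(report: AnalysisReport) -> str:
    """Human-readable markdown summary of a report (side-effect free)."""
    b = report.blocks
    lines = ["# netclass analysis summary", ""]
    if "network" in b:
        net = b["network"]
        lines += [f"Network **{net['name']}**: {net['n_nodes']} nodes, {net['n_edges']} edges.",
                  "Classes: " + ", ".join(f"{c} ({s})" for c, s in net["class_sizes"].items()), ""]
    else:
        lines.append("network: *skipped*")
    if "overlaps" in b:
        lines.append("## Class overlaps")
        for row in _rows(b["overlaps"]["pairwise"]):
            lines.append(f"- {row['class_a']} ∩ {row['class_b']} = {row['overlap']} "
                         f"(OR = {row['odds_ratio']:.2f}, P = {row['p_value']:.2g})")
        lines += [f"- triple overlap = {b['overlaps']['triple_overlap']}", ""]
    if "power_law" in b:
        lines.append("## Degree distribution")
        for side, f in b["power_law"].items():
            if "gamma" in f:
                lines.append(f"- {side}-degree: γ = {f['gamma']:.2f}, r² = {f['r_squared']:.3f}")
        lines.append("")
    if "control" in b and "per_class" in b["control"]:
        lines.append("## Control centrality (normalized class means)")
        for row in _rows(b["control"]["per_class"]):
            lines.append(f"- {row.get('class', row.get('index'))}: {row['mean_normalized_cc']:.4f}")
        lines.append("")
    if "geodesics" in b:
        lines.append("## Geodesic ratios")
        perm = b.get("permutation", {})
        for key, geo in b["geodesics"].items():
            p = perm.get(key, {}).get("p_value")
            ptxt = f", permutation P = {p:.3g}" if p is not None else ""
            lines.append(f"- {key}: GR_first = {geo['gr_first']:.3f}, GR_second = {geo['gr_second']:.3f}, "
                         f"D = {geo['d']:.3f}{ptxt}")
        lines.append("")
    else:
        lines.append("geodesics: *skipped*")
    if "hierarchy" in b and "layer_enrichment" in b["hierarchy"]:
        lines.append("## Hierarchy layers")
        lines.append(f"- best hierarchy score: {b['hierarchy']['best_score']:.3f}; "
                     f"layer sizes: {b['hierarchy']['layer_counts']}")
        for row in _rows(b["hierarchy"]["layer_enrichment"]):
            lines.append(f"- {row['class']} in {row['layer']}: {row['fold']:.2f}-fold "
                         f"(P = {row['p_value']:.2g})")
        lines.append("")
    else:
        lines.append("hierarchy: *skipped*")
    return "\n".join(lines) + "\n"


def _rows(table) -> list[dict]:
    if isinstance(table, pd.DataFrame):
        return table.reset_index().to_dict(orient="records")
    return list(table)
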