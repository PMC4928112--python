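"""Readers and writers for edge lists (TSV / SIF), gene lists and GMT files.

Record filters mirror the cleaning applied to public snapshots of the data
sources (interactome edge filtering, GWAS-catalog trait/p-value filtering):
they are generic operations on user-supplied files — nothing is downloaded.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .network import AnnotationSets, DirectedNetwork, NodeClassMap

logger = logging.getLogger(__name__)

__all__ = [
    "load_edge_list",
    "write_edge_list",
    "load_node_class",
    "build_class_map",
    "filter_disease_gene_records",
    "load_gmt",
]

# header tokens recognized in the first row of a TSV edge list
_HEADER_TOKENS = {"source", "target", "from", "to", "src", "tgt", "gene1", "gene2", "regulator", "regulated"}


def _parse_rows(path: Path, dialect: str) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    drop_predicted_flag: Callable[[list[str]], bool] | None = None,
    name: str | None = None,
) -> DirectedNetwork:
    """Read a directed edge list and return a cleaned :class:`DirectedNetwork`.

    Cleaning removes self-loops, collapses duplicate edges and drops rows for
    which ``drop_predicted_flag(row_fields)`` is true (used to discard
    computationally predicted interactions when the file carries annotation
    columns).  Dropped-row counts are logged.

    Parameters
    ----------
    path
        Edge-list file.  ``tsv`` dialect: one ``source<TAB>target[<TAB>...]``
        row per edge, optional header auto-detected.  ``sif`` dialect:
        ``source<TAB>relation<TAB>target1<TAB>target2...`` rows expand to one
        edge per target.
    dialect
        ``"tsv"`` or ``"sif"``.
    drop_predicted_flag
        Optional predicate on the raw (split) row; matching rows are excluded.

    Raises
    ------
    ValueError
        On a malformed row (fewer columns than the dialect requires, with the
        offending line number) or if the network is empty after cleaning.
    """
    path = Path(path)
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")

    raw_edges: list[tuple[str, str]] = []
    n_flag_dropped = 0
    first_data_row = True
    for lineno, fields in _parse_rows(path, dialect):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: malformed row (need >=2 tab-separated columns)")
        if dialect == "tsv" and first_data_row:
            first_data_row = False
            if fields[0].strip().lower() in _HEADER_TOKENS or fields[1].strip().lower() in _HEADER_TOKENS:
                continue  # header row
        if drop_predicted_flag is not None and drop_predicted_flag(fields):
            n_flag_dropped += 1
            continue
        if dialect == "tsv":
            raw_edges.append((fields[0].strip(), fields[1].strip()))
        else:  # sif
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: SIF row needs source, relation and >=1 target")
            src = fields[0].strip()
            for tgt in fields[2:]:
                if tgt.strip():
                    raw_edges.append((src, tgt.strip()))

    n_self = sum(1 for u, v in raw_edges if u == v)
    kept = {(u, v) for u, v in raw_edges if u != v}
    n_dup = len(raw_edges) - n_self - len(kept)
    logger.info(
        "%s: %d raw edge rows; dropped %d flagged, %d self-loops, %d duplicates -> %d edges",
        path.name, len(raw_edges) + n_flag_dropped, n_flag_dropped, n_self, n_dup, len(kept),
    )
    if not kept:
        raise ValueError(f"{path}: network empty after cleaning")
    return DirectedNetwork.from_edges(kept, name=name or path.stem)


def write_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    """Write the cleaned edge set as sorted two-column TSV (round-trips exactly)."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def load_node_class(path: str | Path, name: str, universe: DirectedNetwork) -> frozenset[str]:
    """Read a one-symbol-per-line gene list and intersect it with the universe.

    Lines starting with ``#`` and blank lines are skipped.  Genes absent from
    the network are dropped with a logged count; an empty intersection is
    legal but logged as a warning.
    """
    if not universe.nodes:
        raise ValueError("universe network is empty")
    listed: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                listed.add(line)
    members = frozenset(listed & universe.nodes)
    dropped = len(listed) - len(members)
    logger.info("class %r: %d listed, %d in network, %d dropped", name, len(listed), len(members), dropped)
    if not members:
        logger.warning("class %r is empty after intersecting with the network", name)
    return members


def build_class_map(universe: DirectedNetwork, class_files: Mapping[str, str | Path]) -> NodeClassMap:
    """Load several class lists against one universe into a :class:`NodeClassMap`."""
    classes = {name: load_node_class(p, name, universe) for name, p in class_files.items()}
    return NodeClassMap(classes=classes, universe=universe)


def filter_disease_gene_records(
    records: pd.DataFrame,
    terms: list[str],
    p_threshold: float,
    gene_col: str = "gene",
    trait_col: str = "trait",
    p_col: str = "p_value",
) -> frozenset[str]:
    """Extract genes whose trait matches a term list at a p-value threshold.

    A record passes when its trait field contains at least one of ``terms``
    (case-insensitive substring match) AND its p-value is strictly below
    ``p_threshold``.  Duplicated genes collapse to one entry.
    """
    if p_threshold <= 0:
        raise ValueError("p_threshold must be positive")
    if not terms:
        raise ValueError("terms must be non-empty")
    missing = [c for c in (gene_col, trait_col, p_col) if c not in records.columns]
    if missing:
        raise ValueError(f"records table missing required column(s): {missing}")
    trait = records[trait_col].astype(str).str.lower()
    term_hit = pd.Series(False, index=records.index)
    for t in terms:
        term_hit |= trait.str.contains(t.lower(), regex=False)
    keep = term_hit & (pd.to_numeric(records[p_col]) < p_threshold)
    return frozenset(records.loc[keep, gene_col].astype(str))


def load_gmt(path: str | Path) -> AnnotationSets:
    """Read a GMT file (``name<TAB>description<TAB>member...`` per row).

    Duplicate set names and rows with fewer than three fields are rejected;
    duplicate members within a row collapse.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs name, description and >=1 member")
            name = fields[0].strip()
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return AnnotationSets(sets=sets, source=str(path))
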