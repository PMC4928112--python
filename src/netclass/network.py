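"""Core containers: directed networks, node classes, annotation sets.

A :class:`DirectedNetwork` is a simple digraph over string gene identifiers:
no self-loops, no duplicate edges.  It is the universe against which every
statistic in the package is defined.  Identifiers are opaque, case-sensitive
strings; no symbol normalization is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import igraph as ig

__all__ = ["DirectedNetwork", "NodeClassMap", "AnnotationSets"]


@dataclass(frozen=True)
class DirectedNetwork:
    """A simple directed graph over string node identifiers.

    Parameters
    ----------
    nodes
        All node identifiers, including isolated nodes.
    edges
        Ordered ``(source, target)`` pairs.  Self-loops are rejected;
        duplicates collapse via set semantics.
    name
        Free-text label used in logs and reports.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    name: str = "network"

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop edge {u!r}->{v!r} not allowed")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint missing from node set: ({u!r}, {v!r})")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        name: str = "network",
    ) -> "DirectedNetwork":
        """Build a network from an edge iterable, silently dropping self-loops."""
        es = frozenset((u, v) for u, v in edges if u != v)
        ns = frozenset(x for e in es for x in e) | frozenset(extra_nodes)
        return cls(nodes=ns, edges=es, name=name)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_order(self) -> list[str]:
        """Deterministic (sorted) node ordering used for all array layouts."""
        return sorted(self.nodes)

    def to_igraph(self) -> ig.Graph:
        """Convert to an :mod:`igraph` graph with nodes in :meth:`node_order`.

        Vertex attribute ``"name"`` carries the node identifier.
        """
        order = self.node_order()
        index = {v: i for i, v in enumerate(order)}
        g = ig.Graph(
            n=len(order),
            edges=[(index[u], index[v]) for u, v in sorted(self.edges)],
            directed=True,
        )
        g.vs["name"] = order
        return g

    def with_edges(self, edges: Iterable[tuple[str, str]], name: str | None = None) -> "DirectedNetwork":
        """Same node set, different edge set (used by the rewiring null)."""
        return DirectedNetwork(
            nodes=self.nodes,
            edges=frozenset(edges),
            name=name if name is not None else self.name,
        )


@dataclass(frozen=True)
class NodeClassMap:
    """Named node classes (e.g. DTN / SMN / GGN) mapped onto one network.

    Every class member must be a node of ``universe``; loaders intersect
    lists with the universe before constructing the map.  The insertion
    order of ``classes`` is meaningful: it is the default upstream-to-
    downstream ordering used by the synthetic generator.
    """

    classes: Mapping[str, frozenset[str]]
    universe: DirectedNetwork

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", dict(self.classes))
        for cname, members in self.classes.items():
            stray = members - self.universe.nodes
            if stray:
                raise ValueError(
                    f"class {cname!r} has {len(stray)} members outside the universe "
                    f"(e.g. {sorted(stray)[:3]})"
                )

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.classes[name]

    def names(self) -> list[str]:
        return list(self.classes)


@dataclass(frozen=True)
class AnnotationSets:
    """Named annotation sets (e.g. GO cellular-component terms) from a GMT file.

    Membership in a network universe is checked at enrichment time, not here.
    """

    sets: Mapping[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", dict(self.sets))

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)
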