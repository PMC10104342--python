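"""Model structure: nodes, parent bindings, validation, ordering, rendering.

A simulation model is a directed acyclic graph. Each node is a
:class:`NodeSpec` naming a generating function and binding its parameters
either to constants or, via :class:`NodeRef`, to the values of parent nodes.
``build_graph`` validates the collection (unique names, resolvable
references, at most one selection and one stratify node, acyclicity) and
expands flat plates into index-suffixed i.i.d. replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

import networkx as nx

from .errors import (
    CycleError,
    DuplicateNameError,
    KindError,
    UnresolvedReferenceError,
)

NODE_KINDS = ("standard", "selection", "missing", "stratify")


@dataclass(frozen=True)
class NodeRef:
    """A binding value that refers to another node's sampled value.

    In a node's ``kwargs``, ``NodeRef("A")`` means "pass node A's value for
    the current sample"; any other value is passed through as a literal.
    """

    name: str

    def __repr__(self) -> str:  # concise in error messages
        return f"NodeRef({self.name!r})"


@dataclass
class NodeSpec:
    """One variable of the simulation model.

    Parameters
    ----------
    name:
        Unique, non-empty identifier.
    func:
        The generating callable. Called once per sample with ``kwargs``
        (NodeRefs replaced by parent values). If the callable accepts a
        parameter named ``rng``, the engine injects its seeded
        ``numpy.random.Generator``. ``None`` only for ``kind="missing"``.
    kwargs:
        Parameter bindings; values are literals or :class:`NodeRef`.
    kind:
        ``standard`` (a data column), ``selection`` (per-sample accept/reject
        predicate), ``missing`` (masked copy of another node), or
        ``stratify`` (per-sample stratum label).
    observed:
        Whether the node contributes a column to the output table.
    plate:
        Optional ``(plate_id, k)``: replicate this node k times as
        ``name_1 .. name_k``, with NodeRefs between same-plate nodes
        rewritten replicate-locally.
    underlying, mask:
        For ``kind="missing"`` only: the node whose values are masked, and
        the truth-valued node that decides which entries become missing.
    """

    name: str
    func: Optional[Callable[..., Any]] = None
    kwargs: dict[str, Any] = field(default_factory=dict)
    kind: str = "standard"
    observed: bool = True
    plate: Optional[tuple[str, int]] = None
    underlying: Optional[str] = None
    mask: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValueError("node name must be a non-empty string")
        if self.kind not in NODE_KINDS:
            raise KindError(
                f"node {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {NODE_KINDS}"
            )
        if self.kind == "missing":
            if self.func is not None or self.kwargs:
                raise KindError(
                    f"missing node {self.name!r} takes no function/kwargs; "
                    "it is defined by its underlying and mask nodes"
                )
            if not self.underlying or not self.mask:
                raise KindError(
                    f"missing node {self.name!r} must name both an "
                    "underlying node and a mask node"
                )
        else:
            if self.func is None:
                raise KindError(f"node {self.name!r} has no generating function")
            if self.underlying or self.mask:
                raise KindError(
                    f"node {self.name!r}: underlying/mask are only valid "
                    "for kind='missing'"
                )
        if self.plate is not None:
            plate_id, count = self.plate
            if not isinstance(count, int) or count < 1:
                raise ValueError(
                    f"node {self.name!r}: plate count must be an integer >= 1"
                )

    def parent_names(self) -> list[str]:
        """Names of this node's parents, in binding declaration order."""
        if self.kind == "missing":
            return [self.underlying, self.mask]
        seen: list[str] = []
        for value in self.kwargs.values():
            if isinstance(value, NodeRef) and value.name not in seen:
                seen.append(value.name)
        return seen


def make_missing_node(name: str, underlying: str, mask: str) -> NodeSpec:
    """Declare a node whose value is ``underlying``'s value wherever ``mask``
    is false and the missing sentinel wherever ``mask`` is true.

    ``underlying`` and ``mask`` must name standard nodes of the same graph;
    the mask's function must return a truth value per sample. Validation
    against the graph happens in :func:`build_graph`.
    """
    return NodeSpec(name=name, kind="missing", underlying=underlying, mask=mask)


@dataclass
class Graph:
    """A validated simulation model.

    ``nodes`` preserves declaration order (plates already expanded);
    ``edges`` is the derived set of ``(parent, child)`` pairs.
    """

    name: str
    nodes: list[NodeSpec]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self._by_name = {spec.name: spec for spec in self.nodes}

    def __getitem__(self, name: str) -> NodeSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def node_names(self) -> list[str]:
        return [spec.name for spec in self.nodes]

    def nodes_of_kind(self, kind: str) -> list[NodeSpec]:
        return [spec for spec in self.nodes if spec.kind == kind]

    @property
    def selection_node(self) -> Optional[NodeSpec]:
        found = self.nodes_of_kind("selection")
        return found[0] if found else None

    @property
    def stratify_node(self) -> Optional[NodeSpec]:
        found = self.nodes_of_kind("stratify")
        return found[0] if found else None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return (
            self.name == other.name
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


def _expand_plates(specs: list[NodeSpec]) -> list[NodeSpec]:
    """Replicate plate-tagged nodes k times with index-suffixed names.

    Only flat plates are supported: a plate is a set of nodes sharing a
    plate_id, replicated jointly. NodeRefs between nodes of the same plate
    are rewritten to the replicate-local name; references from outside a
    plate to a plated node are left untouched (and will fail resolution).
    """
    plate_counts: dict[str, int] = {}
    plate_members: dict[str, set[str]] = {}
    for spec in specs:
        if spec.plate is None:
            continue
        pid, count = spec.plate
        if pid in plate_counts and plate_counts[pid] != count:
            raise ValueError(
                f"plate {pid!r} declared with conflicting counts "
                f"{plate_counts[pid]} and {count}"
            )
        plate_counts[pid] = count
        plate_members.setdefault(pid, set()).add(spec.name)

    if not plate_counts:
        return list(specs)

    expanded: list[NodeSpec] = []
    for spec in specs:
        if spec.plate is None:
            expanded.append(spec)
            continue
        pid, count = spec.plate
        members = plate_members[pid]
        for i in range(1, count + 1):
            kwargs = {
                key: (
                    NodeRef(f"{value.name}_{i}")
                    if isinstance(value, NodeRef) and value.name in members
                    else value
                )
                for key, value in spec.kwargs.items()
            }
            replica = dataclasses.replace(
                spec,
                name=f"{spec.name}_{i}",
                kwargs=kwargs,
                plate=None,
                underlying=(
                    f"{spec.underlying}_{i}"
                    if spec.underlying in members
                    else spec.underlying
                ),
                mask=f"{spec.mask}_{i}" if spec.mask in members else spec.mask,
            )
            expanded.append(replica)
    return expanded


def build_graph(specs: list[NodeSpec], name: str = "model") -> Graph:
    """Validate node specs into a :class:`Graph`.

    Checks, in order: non-empty spec list, unique names (pre- and
    post-expansion), plate expansion, resolvable references, kind
    constraints (at most one selection node, at most one stratify node,
    missing nodes masking standard nodes only), no self-loops, and
    acyclicity of the expanded graph.

    Raises
    ------
    DuplicateNameError, UnresolvedReferenceError, CycleError, KindError
    """
    if not specs:
        raise ValueError("cannot build a graph from an empty spec list")

    seen: set[str] = set()
    for spec in specs:
        if spec.name in seen:
            raise DuplicateNameError(f"duplicate node name {spec.name!r}")
        seen.add(spec.name)

    expanded = _expand_plates(specs)
    names = set()
    for spec in expanded:
        if spec.name in names:
            raise DuplicateNameError(
                f"plate expansion produced duplicate node name {spec.name!r}"
            )
        names.add(spec.name)
    by_name = {spec.name: spec for spec in expanded}

    if len([s for s in expanded if s.kind == "selection"]) > 1:
        raise KindError("at most one selection node is allowed per graph")
    if len([s for s in expanded if s.kind == "stratify"]) > 1:
        raise KindError("at most one stratify node is allowed per graph")

    edges: set[tuple[str, str]] = set()
    for spec in expanded:
        for parent in spec.parent_names():
            if parent not in by_name:
                raise UnresolvedReferenceError(
                    f"node {spec.name!r} references unknown node {parent!r}"
                )
            if parent == spec.name:
                raise CycleError([spec.name])
            edges.add((parent, spec.name))
        if spec.kind == "missing":
            for role, ref in (("underlying", spec.underlying), ("mask", spec.mask)):
                if by_name[ref].kind != "standard":
                    raise KindError(
                        f"missing node {spec.name!r}: {role} node {ref!r} "
                        f"must be a standard node, got kind "
                        f"{by_name[ref].kind!r}"
                    )

    digraph = nx.DiGraph()
    digraph.add_nodes_from(by_name)
    digraph.add_edges_from(edges)
    try:
        cycle = nx.find_cycle(digraph, orientation="original")
    except nx.NetworkXNoCycle:
        pass
    else:
        raise CycleError([u for u, _, _ in cycle])

    return Graph(name=name, nodes=expanded, edges=edges)


def topological_order(graph: Graph) -> list[str]:
    """Node names with every parent before its children.

    Ties are broken by declaration order, so the result (and hence CSV
    column order) is deterministic for a given graph.
    """
    index = {spec.name: i for i, spec in enumerate(graph.nodes)}
    digraph = nx.DiGraph()
    digraph.add_nodes_from(graph.node_names())
    digraph.add_edges_from(graph.edges)
    return list(nx.lexicographical_topological_sort(digraph, key=index.get))


_DOT_SHAPE = {
    "standard": "ellipse",
    "selection": "diamond",
    "missing": "box",
    "stratify": "folder",
}


def render_graph(graph: Graph) -> str:
    """Render the graph as DOT text, one vertex per node and one arc per
    edge, with node shape distinguishing the four kinds.

    Output is deterministic: vertices in declaration order, arcs sorted.
    """
    lines = [f'digraph "{graph.name}" {{']
    for spec in graph.nodes:
        style = ', style=dashed' if not spec.observed else ""
        lines.append(
            f'  "{spec.name}" [shape={_DOT_SHAPE[spec.kind]}{style}];'
        )
    for parent, child in sorted(graph.edges):
        lines.append(f'  "{parent}" -> "{child}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
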