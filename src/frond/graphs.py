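"""Graph construction from parsed LGL statements.

Evaluating a statement list yields a :class:`Registry` of graph objects:
named graphs (``label: ...;``) plus one anonymous graph per ``@``-free
unlabeled statement.  Using a named label as an item pastes a *copy* of
that graph (fresh node instances); prefixing it with ``@`` extends the
stored object in place.  Within one graph object, plain items with the
same label denote the same node, so a pipeline can also be written as a
flat list of edge statements and recovered with :meth:`Registry.pipeline`.

Arrow semantics: node→node adds an edge; an arrow into a graph-valued
operand targets its roots (in-degree 0), an arrow out of one leaves from
its leaves (out-degree 0), with root/leaf sets snapshotted when the
operand is resolved.  Forks connect the parent to each branch head, a
void ``.`` branch is elided (its children attach directly to the parent).

LGL can express cyclic graphs; :func:`validate_dag` reports a witnessing
cycle for the execution layers that require a DAG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .lgl import (
    Chain,
    Fork,
    Item,
    ItemSet,
    LglError,
    Statement,
    parse,
)

__all__ = [
    "Node",
    "Graph",
    "Registry",
    "DagReport",
    "EvaluationError",
    "UndefinedReferenceError",
    "VoidNodeError",
    "evaluate",
    "compile_lgl",
    "connect",
    "roots",
    "leaves",
    "validate_dag",
    "to_dot",
    "to_json",
]


class EvaluationError(LglError):
    """Semantic error while turning statements into graphs."""


class UndefinedReferenceError(EvaluationError):
    """``@X`` used where no named graph ``X`` exists."""


class VoidNodeError(EvaluationError):
    """The void item ``.`` appeared outside a fork branch position."""


@dataclass(eq=False)
class Node:
    """One node instance.  ``uid`` is unique within a registry; the label
    is not (pasting a named graph twice repeats its labels)."""

    label: str
    uid: str
    flags: set = field(default_factory=set)


class Graph:
    """Directed graph: node instances plus an ordered, duplicate-free edge
    list.  Edge order is creation order; it later fixes the argument order
    of multi-input pipeline functions."""

    def __init__(self, name: str | None = None):
        self.name = name
        self.nodes: dict[str, Node] = {}  # uid -> Node, insertion ordered
        self.edges: list[tuple[str, str]] = []
        self._edge_set: set[tuple[str, str]] = set()

    def add_node(self, node: Node) -> Node:
        self.nodes[node.uid] = node
        return node

    def add_edge(self, src: str, dst: str) -> None:
        if src not in self.nodes or dst not in self.nodes:
            raise KeyError("edge endpoint not in graph")
        if (src, dst) not in self._edge_set:
            self._edge_set.add((src, dst))
            self.edges.append((src, dst))

    def node_by_label(self, label: str) -> Node | None:
        """First (by insertion order) node carrying *label*, if any."""
        for node in self.nodes.values():
            if node.label == label:
                return node
        return None

    def in_degree(self, uid: str) -> int:
        return sum(1 for _, d in self.edges if d == uid)

    def out_degree(self, uid: str) -> int:
        return sum(1 for s, _ in self.edges if s == uid)

    def edge_labels(self) -> set[tuple[str, str]]:
        """Edges as (source label, target label) pairs — handy in tests."""
        return {
            (self.nodes[s].label, self.nodes[d].label) for s, d in self.edges
        }

    def labels(self) -> list[str]:
        return [n.label for n in self.nodes.values()]

    def __len__(self) -> int:
        return len(self.nodes)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        name = self.name or "<anonymous>"
        return f"Graph({name}: {len(self.nodes)} nodes, {len(self.edges)} edges)"


def roots(graph: Graph) -> list[Node]:
    """Nodes with no incoming edges, in insertion order."""
    targets = {d for _, d in graph.edges}
    return [n for n in graph.nodes.values() if n.uid not in targets]


def leaves(graph: Graph) -> list[Node]:
    """Nodes with no outgoing edges, in insertion order."""
    sources = {s for s, _ in graph.edges}
    return [n for n in graph.nodes.values() if n.uid not in sources]


class Registry:
    """All graph objects produced by evaluating one LGL program, in
    definition order."""

    def __init__(self):
        self.named: dict[str, Graph] = {}
        self.anonymous: list[Graph] = []
        self.order: list[Graph] = []

    def all_graphs(self) -> list[Graph]:
        return list(self.order)

    def __len__(self) -> int:
        return len(self.order)

    def pipeline(self) -> Graph:
        """Union of every graph in the registry with same-label node
        unification — the single executable graph behind a program written
        either as one structured statement or as a flat edge list.

        The first occurrence of a label supplies the node instance; flags
        from later same-label nodes are merged onto it.  Edges keep their
        global creation order.
        """
        merged = Graph(name="pipeline")
        by_label: dict[str, Node] = {}
        for g in self.order:
            for node in g.nodes.values():
                if node.label not in by_label:
                    rep = Node(node.label, f"p{len(by_label)}", set(node.flags))
                    by_label[node.label] = merged.add_node(rep)
                else:
                    by_label[node.label].flags |= node.flags
            for s, d in g.edges:
                merged.add_edge(
                    by_label[g.nodes[s].label].uid,
                    by_label[g.nodes[d].label].uid,
                )
        return merged


# ---------------------------------------------------------------------------
# Statement evaluation
# ---------------------------------------------------------------------------


@dataclass
class _Operand:
    """A resolved operand: the nodes it contributed plus root/leaf
    snapshots taken at resolution time (so ``X -> G -> Y`` uses G's
    original roots and leaves)."""

    nodes: list[Node]
    roots: list[Node]
    leaves: list[Node]


class _Evaluator:
    def __init__(self):
        self.registry = Registry()
        self._uid = 0
        self._stmt_members: set[str] = set()

    def fresh_uid(self) -> str:
        uid = f"n{self._uid}"
        self._uid += 1
        return uid

    # -- program -----------------------------------------------------------

    def run(self, statements: list[Statement]) -> Registry:
        for stmt in statements:
            self.statement(stmt)
        return self.registry

    def statement(self, stmt: Statement) -> Graph:
        refs = _referenced_names(stmt.expr)
        for name, line in refs:
            if name not in self.registry.named:
                raise UndefinedReferenceError(
                    f"'@{name}' does not reference a named graph", line
                )
        if refs:
            # the statement extends the first referenced object in place
            target = self.registry.named[refs[0][0]]
            if stmt.label is not None:
                self.registry.named[stmt.label] = target
        elif stmt.label is not None:
            target = Graph(name=stmt.label)
            self.registry.named[stmt.label] = target
            self.registry.order.append(target)
        else:
            target = Graph()
            self.registry.anonymous.append(target)
            self.registry.order.append(target)
        # '@' references denote the graph as it stood before this statement
        self._stmt_members = set(target.nodes)
        self.chain(stmt.expr, target)
        return target

    # -- expressions -------------------------------------------------------

    def chain(self, chain: Chain, g: Graph) -> _Operand:
        prev = self.resolve(chain.operands[0], g)
        first = prev
        for arrow, operand in zip(chain.arrows, chain.operands[1:]):
            cur = self.resolve(operand, g)
            direction = "right" if arrow == "->" else "left"
            _connect_ops(prev, cur, direction, g)
            prev = cur
        return first

    def resolve(self, operand, g: Graph) -> _Operand:
        if isinstance(operand, ItemSet):
            return self.resolve_itemset(operand, g)
        if isinstance(operand, Fork):
            return self.resolve_fork(operand, g)
        raise TypeError(type(operand).__name__)

    def resolve_itemset(self, itemset: ItemSet, g: Graph) -> _Operand:
        nodes: list[Node] = []
        rts: list[Node] = []
        lvs: list[Node] = []
        for item in itemset.items:
            if item.is_void:
                raise VoidNodeError(
                    "void item '.' is only valid as a fork branch", item.line
                )
            part = self.resolve_item(item, g)
            nodes.extend(part.nodes)
            rts.extend(part.roots)
            lvs.extend(part.leaves)
        return _Operand(nodes, rts, lvs)

    def resolve_item(self, item: Item, g: Graph) -> _Operand:
        if item.ref:
            ref = self.registry.named[item.name]
            if ref is g:
                members = self._stmt_members
            else:
                members = set(ref.nodes)
                self._absorb(ref, g)
            sub = [n for n in g.nodes.values() if n.uid in members]
            return _snapshot(sub, g)
        if item.name in self.registry.named:
            # paste a fresh copy of the named graph
            source = self.registry.named[item.name]
            mapping: dict[str, Node] = {}
            for node in source.nodes.values():
                copy = Node(node.label, self.fresh_uid(), set(node.flags))
                mapping[node.uid] = g.add_node(copy)
            for s, d in source.edges:
                g.add_edge(mapping[s].uid, mapping[d].uid)
            return _snapshot(list(mapping.values()), g)
        node = g.node_by_label(item.name)
        if node is None:
            node = g.add_node(Node(item.name, self.fresh_uid(), set(item.flags)))
        else:
            node.flags |= item.flags
        return _Operand([node], [node], [node])

    def resolve_fork(self, fork: Fork, g: Graph) -> _Operand:
        parent = self.resolve(fork.parent, g)
        nodes = list(parent.nodes)
        for branch in fork.branches:
            nodes.extend(self._attach_branch(parent, branch, g))
        lvs = [n for n in nodes if g.out_degree(n.uid) == 0]
        return _Operand(nodes, list(parent.roots), lvs)

    def _attach_branch(self, parent: _Operand, branch, g: Graph) -> list[Node]:
        """Connect *parent* to a fork branch; returns branch nodes."""
        if isinstance(branch, ItemSet) and all(i.is_void for i in branch.items):
            return []  # void leaf branch: elided entirely
        if isinstance(branch, Fork) and _is_void_set(branch.parent):
            # void intermediate: children attach directly to the parent
            nodes: list[Node] = []
            for sub in branch.branches:
                nodes.extend(self._attach_branch(parent, sub, g))
            return nodes
        op = self.resolve(branch, g)
        _connect_ops(parent, op, "right", g)
        return op.nodes

    # -- reference plumbing ------------------------------------------------

    def _absorb(self, other: Graph, g: Graph) -> None:
        """Merge a second referenced graph's structure into the target."""
        for node in other.nodes.values():
            if node.uid not in g.nodes:
                g.add_node(node)
        for s, d in other.edges:
            g.add_edge(s, d)


def _is_void_set(operand) -> bool:
    return isinstance(operand, ItemSet) and all(i.is_void for i in operand.items)


def _referenced_names(chain: Chain) -> list[tuple[str, int]]:
    """``@``-referenced names in a chain, in source order."""
    out: list[tuple[str, int]] = []

    def walk(op):
        if isinstance(op, ItemSet):
            for item in op.items:
                if item.ref:
                    out.append((item.name, item.line))
        elif isinstance(op, Fork):
            walk(op.parent)
            for b in op.branches:
                walk(b)

    for op in chain.operands:
        walk(op)
    return out


def _snapshot(nodes: list[Node], g: Graph) -> _Operand:
    uids = {n.uid for n in nodes}
    targets = {d for s, d in g.edges if s in uids and d in uids}
    sources = {s for s, d in g.edges if s in uids and d in uids}
    return _Operand(
        nodes,
        [n for n in nodes if n.uid not in targets],
        [n for n in nodes if n.uid not in sources],
    )


def _connect_ops(left: _Operand, right: _Operand, direction: str, g: Graph):
    if direction == "left":
        left, right = right, left
    for src in left.leaves:
        for dst in right.roots:
            g.add_edge(src.uid, dst.uid)


def evaluate(statements: list[Statement]) -> Registry:
    """Build graph objects from parsed statements (see module docstring)."""
    return _Evaluator().run(statements)


def compile_lgl(text: str) -> Registry:
    """Parse + evaluate in one call."""
    return evaluate(parse(text))


def connect(left, right, direction: str, graph: Graph) -> None:
    """Connect two resolved operands (node lists) inside *graph*.

    *left*/*right* are lists of :class:`Node`; graph-valued operands should
    be passed through their root/leaf snapshots (see :func:`roots` /
    :func:`leaves`).  ``direction`` is ``"right"`` or ``"left"``.
    """
    _connect_ops(
        _snapshot(list(left), graph), _snapshot(list(right), graph),
        direction, graph,
    )


# ---------------------------------------------------------------------------
# DAG validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DagReport:
    is_dag: bool
    cycle: tuple = ()  # node labels of one witnessing cycle, closed

    def __bool__(self) -> bool:
        return self.is_dag


def validate_dag(graph: Graph) -> DagReport:
    """Check acyclicity; on failure return one witnessing cycle as a closed
    label sequence (first == last)."""
    succ: dict[str, list[str]] = {uid: [] for uid in graph.nodes}
    for s, d in graph.edges:
        succ[s].append(d)
    WHITE, GREY, BLACK = 0, 1, 2
    color = {uid: WHITE for uid in graph.nodes}
    parent: dict[str, str | None] = {}
    for start in graph.nodes:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        color[start] = GREY
        parent[start] = None
        while stack:
            uid, idx = stack[-1]
            if idx < len(succ[uid]):
                stack[-1] = (uid, idx + 1)
                nxt = succ[uid][idx]
                if color[nxt] == GREY:
                    # unwind the grey path to build the witness
                    cycle = [nxt, uid]
                    cur = uid
                    while cur != nxt:
                        cur = parent[cur]
                        cycle.append(cur)
                    cycle.reverse()  # nxt ... uid nxt
                    labels = tuple(graph.nodes[u].label for u in cycle)
                    return DagReport(False, labels)
                if color[nxt] == WHITE:
                    color[nxt] = GREY
                    parent[nxt] = uid
                    stack.append((nxt, 0))
            else:
                color[uid] = BLACK
                stack.pop()
    return DagReport(True)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def to_dot(graph: Graph, annotations: dict[str, str] | None = None) -> str:
    """Render a graph as Graphviz DOT text.

    Nodes flagged ``F`` (file producers) get straight corners
    (``shape=box``); everything else is an ellipse.  Node ids are the
    internal uids so duplicate labels stay distinct; the displayed label is
    the plain node label.  *annotations* maps node labels to tooltip text
    (used for docstrings).
    """
    annotations = annotations or {}
    lines = ["digraph {"]
    for node in graph.nodes.values():
        shape = "box" if "F" in node.flags else "ellipse"
        attrs = [f'label="{_dot_escape(node.label)}"', f"shape={shape}"]
        tip = annotations.get(node.label)
        if tip:
            attrs.append(f'tooltip="{_dot_escape(tip)}"')
        lines.append(f'  "{node.uid}" [{", ".join(attrs)}];')
    for s, d in graph.edges:
        lines.append(f'  "{s}" -> "{d}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def to_json(graph: Graph) -> str:
    """Machine-readable graph dump: nodes (uid/label/flags) + ordered edges."""
    payload = {
        "name": graph.name,
        "nodes": [
            {"uid": n.uid, "label": n.label, "flags": sorted(n.flags)}
            for n in graph.nodes.values()
        ],
        "edges": [[s, d] for s, d in graph.edges],
    }
    return json.dumps(payload, indent=2) + "\n"
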