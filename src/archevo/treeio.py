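"""Rooted phylogeny data model with newick reading/writing.

Trees are treated as rooted exactly as written; no implicit rerooting is
performed (ancestral-state polarity depends on the root).  Polytomies are
accepted.  Newick parsing/writing is delegated to dendropy; the package
works with a small immutable-topology node model of its own so that node
identifiers are stable integers assigned in preorder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Malformed newick or inconsistent tree structure."""


@dataclass(eq=False)
class Node:
    id: int
    name: Optional[str] = None
    length: Optional[float] = None
    parent: Optional["Node"] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id}, {self.name!r})"


class Phylogeny:
    """A rooted tree with uniquely named tips and stable preorder node ids."""

    def __init__(self, root: Node):
        self.root = root
        self._nodes: list[Node] = list(self._preorder(root))
        for i, node in enumerate(self._nodes):
            node.id = i
        names = [n.name for n in self.tips()]
        dupes = {x for x in names if names.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate tip names: {sorted(dupes)}")
        if any(n.name is None for n in self.tips()):
            raise TreeError("every tip must carry a taxon name")
        for n in self._nodes:
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length on node {n.name or n.id}")
        self._by_name = {n.name: n for n in self._nodes if n.name is not None}

    @staticmethod
    def _preorder(root: Node) -> Iterator[Node]:
        stack = [root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    # -- traversal -----------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return iter(self._nodes)

    def postorder(self) -> Iterator[Node]:
        return reversed(self._nodes)

    def nodes(self) -> list[Node]:
        return list(self._nodes)

    def tips(self) -> list[Node]:
        return [n for n in self._nodes if n.is_tip]

    def node_by_name(self, name: str) -> Node:
        try:
            return self._by_name[name]
        except KeyError:
            raise TreeError(f"no node named {name!r}") from None

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]  # type: ignore[misc]

    def mrca(self, names: Iterable[str]) -> Node:
        """Lowest node ancestral to all listed tips (a single tip is its own MRCA)."""
        names = list(names)
        if not names:
            raise TreeError("mrca requires at least one tip name")
        nodes = [self.node_by_name(n) for n in names]
        for node in nodes:
            if not node.is_tip:
                raise TreeError(f"{node.name!r} is not a tip")
        paths = []
        for node in nodes:
            path = []
            cur: Optional[Node] = node
            while cur is not None:
                path.append(cur)
                cur = cur.parent
            paths.append(list(reversed(path)))
        mrca = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self._nodes if n is not self.root)

    def copy(self) -> "Phylogeny":
        return read_newick(write_newick(self))


def _convert(dnode: dendropy.Node, parent: Optional[Node]) -> Node:
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
    else:
        name = dnode.label
    node = Node(id=-1, name=name, length=dnode.edge.length, parent=parent)
    node.children = [_convert(child, node) for child in dnode.child_nodes()]
    return node


def read_newick(text: str) -> Phylogeny:
    """Parse one rooted newick tree (the outermost clade is the root)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error classes
        raise TreeError(f"newick parse error: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise TreeError("tree has no tips")
    root = _convert(dtree.seed_node, None)
    return Phylogeny(root)


def _emit(node: Node) -> str:
    label = node.name or ""
    if "(" in label or ")" in label or "," in label or ";" in label or " " in label:
        label = "'" + label.replace("'", "''") + "'"
    length = "" if node.length is None else f":{node.length:.10g}"
    if node.is_tip:
        return f"{label}{length}"
    inner = ",".join(_emit(c) for c in node.children)
    return f"({inner}){label}{length}"


def write_newick(tree: Phylogeny) -> str:
    """Serialize; branch lengths are re-emitted to 10 significant digits."""
    return _emit(tree.root) + ";"


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())
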