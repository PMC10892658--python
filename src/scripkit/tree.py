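"""Support-annotated phylogenies.

A :class:`SupportTree` is a lightweight rooted/unrooted tree whose internal
nodes carry clade-confidence statistics: ultrafast-bootstrap-style support
as a percentage, and optionally SH-aLRT (0-100) and approximate-Bayes
(0-1) values.  Newick parsing is delegated to dendropy; internal-node
labels are interpreted as either a bare support number (bootstrap %), an
IQ-TREE-style ``sh/abayes/bs`` slash-triplet, or an opaque clade name
(support absent, never coerced to 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["Support", "Node", "SupportTree", "read_newick", "parse_newick", "write_newick"]


@dataclass
class Support:
    bootstrap_pct: Optional[float] = None
    sh_alrt: Optional[float] = None
    abayes: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bootstrap_pct is not None and not (0 <= self.bootstrap_pct <= 100):
            raise ValueError(f"bootstrap_pct {self.bootstrap_pct} outside [0, 100]")


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[Support] = None,
        children: Optional[list["Node"]] = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        for c in children or []:
            self.add_child(c)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())

    def copy(self) -> "Node":
        new = Node(self.name, self.length,
                   Support(**vars_of(self.support)) if self.support else None)
        for c in self.children:
            new.add_child(c.copy())
        return new


def vars_of(s: Support) -> dict:
    return {"bootstrap_pct": s.bootstrap_pct, "sh_alrt": s.sh_alrt, "abayes": s.abayes}


@dataclass
class SupportTree:
    root: Node
    rooted: bool = False

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def copy(self) -> "SupportTree":
        return SupportTree(self.root.copy(), self.rooted)

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised to the side NOT
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for n in self.preorder():
            if n is self.root or n.is_leaf:
                continue
            side = n.leaf_names()
            if anchor in side:
                side = all_leaves - side
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                out.add(side)
        return out

    def find_clade(self, leaf_set: frozenset[str]) -> Optional[Node]:
        for n in self.preorder():
            if n.leaf_names() == leaf_set:
                return n
        return None

    def mrca(self, names: Iterable[str]) -> Node:
        target = frozenset(names)
        best = self.root
        changed = True
        while changed:
            changed = False
            for c in best.children:
                if target <= c.leaf_names():
                    best = c
                    changed = True
                    break
        return best

    def prune(self, drop: Iterable[str]) -> "SupportTree":
        """Return a copy with the named leaves removed and unary nodes
        collapsed (branch lengths summed, support of the lower edge kept)."""
        drop = set(drop)
        root = self.root.copy()

        def rec(node: Node) -> Optional[Node]:
            if node.is_leaf:
                return None if node.name in drop else node
            kept = [rec(c) for c in node.children]
            kept = [c for c in kept if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                return child
            node.children = []
            for c in kept:
                node.add_child(c)
            return node

        new_root = rec(root)
        if new_root is None:
            raise ValueError("pruning removed every leaf")
        new_root.parent = None
        return SupportTree(new_root, self.rooted)

    def ladderized(self) -> "SupportTree":
        """Copy with children ordered by descending subtree size, ties by
        smallest member id; makes traversal order deterministic."""
        t = self.copy()
        for n in t.preorder():
            n.children.sort(key=lambda c: (-len(c.leaf_names()), min(c.leaf_names())))
            for c in n.children:
                c.parent = n
        return t

    def to_newick(self) -> str:
        return write_newick(self)


# -- Newick I/O ------------------------------------------------------------

def _interpret_label(label: Optional[str]) -> tuple[Optional[str], Optional[Support]]:
    """An internal label is a bare bootstrap %, an sh/abayes/bs triplet, or
    an opaque name."""
    if label is None or label == "":
        return None, None
    if "/" in label:
        parts = label.split("/")
        if len(parts) == 3:
            try:
                sh, ab, bs = (float(p) for p in parts)
                return None, Support(bootstrap_pct=bs, sh_alrt=sh, abayes=ab)
            except ValueError:
                pass
        return label, None
    try:
        return None, Support(bootstrap_pct=float(label))
    except ValueError:
        return label, None


def parse_newick(text: str) -> SupportTree:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"Newick parse error: {exc}") from None

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            return Node(name=name, length=dnode.edge.length)
        name, support = _interpret_label(dnode.label)
        node = Node(name=name, length=dnode.edge.length, support=support)
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    names = [n.name for n in root.leaves()]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf ids in tree: {dup}")
    return SupportTree(root, rooted=len(root.children) == 2)


def read_newick(path) -> SupportTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _fmt_num(x: float) -> str:
    s = f"{x:.10g}"
    return s


def _node_label(n: Node) -> str:
    if n.support is not None:
        s = n.support
        if s.sh_alrt is not None or s.abayes is not None:
            return (
                f"{_fmt_num(s.sh_alrt if s.sh_alrt is not None else 0)}/"
                f"{_fmt_num(s.abayes if s.abayes is not None else 0)}/"
                f"{_fmt_num(s.bootstrap_pct if s.bootstrap_pct is not None else 0)}"
            )
        if s.bootstrap_pct is not None:
            return _fmt_num(s.bootstrap_pct)
    return n.name or ""


def write_newick(tree: SupportTree) -> str:
    def rec(n: Node) -> str:
        if n.is_leaf:
            base = n.name or ""
        else:
            base = "(" + ",".join(rec(c) for c in n.children) + ")" + _node_label(n)
        if n.length is not None:
            base += f":{_fmt_num(n.length)}"
        return base

    return rec(tree.root) + ";"
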