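"""A small phylogenetic tree structure with Newick I/O and bipartitions.

Trees are node-based; an unrooted tree is stored rooted at an arbitrary
internal node with three or more children.  Support values live on
internal nodes (the convention used by the ``label:length`` Newick
dialect, where an internal node's label is its support).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class Node:
    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        yield self
        for child in self.children:
            yield from child.walk()

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def copy(self) -> "Node":
        dup = Node(name=self.name, length=self.length, support=self.support)
        for child in self.children:
            dup.add(child.copy())
        return dup


@dataclass
class Tree:
    root: Node
    rooted: bool = False

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), rooted=self.rooted)

    # -- bipartitions -----------------------------------------------------
    def bipartitions(self, nontrivial_only: bool = True) -> set[frozenset[str]]:
        """Canonical leaf-set bipartitions, one per internal edge.

        Each edge splits the leaves in two; the side *not* containing the
        lexicographically smallest leaf is the canonical representative, so
        sets compare across differently rooted trees.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            below = frozenset(node.leaf_names())
            side = below if anchor not in below else all_leaves - below
            if nontrivial_only and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            out.add(side)
        return out

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"leaf {name!r} not in tree")

    # -- Newick -----------------------------------------------------------
    def to_newick(self, decimals: int = 6, supports: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if supports and node.support is not None:
                    label = f"{node.support:g}"
                elif node.name:
                    label = node.name
                s = f"({inner}){label}"
            if node.length is not None:
                s += f":{node.length:.{decimals}f}"
            return s

        return fmt(self.root) + ";"


def parse_newick(text: str, rooted: Optional[bool] = None) -> Tree:
    """Parse a Newick string (labels, branch lengths, internal supports)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses in Newick")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character {s[pos]!r} at {pos}")
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick at {pos}: {s[pos:]!r}")
    if rooted is None:
        rooted = len(root.children) == 2
    return Tree(root, rooted=rooted)


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())
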