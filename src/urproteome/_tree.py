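"""Minimal rooted-tree container used by the parsimony engine.

Trees are stored as rooted structures with unlabeled internal nodes and
string-labeled leaves.  An unrooted binary tree on n taxa is represented as a
rooted binary tree whose root has exactly two children (the root marks a point
on one edge of the unrooted tree); ordered-character parsimony lengths are
invariant to where that point is placed, so the representation is lossless for
scoring purposes.  Polytomies are allowed (consensus trees, star trees).
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional


class Node:
    __slots__ = ("children", "parent", "taxon")

    def __init__(self, taxon: Optional[str] = None):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.taxon = taxon

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.taxon or 'internal'}>"


class Tree:
    """A rooted tree over string-labeled leaves."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        """Parse a newick string (labels on leaves; branch lengths ignored)."""
        s = newick.strip().rstrip(";")
        pos = 0

        def parse() -> Node:
            nonlocal pos
            node = Node()
            if s[pos] == "(":
                pos += 1
                while True:
                    node.add(parse())
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
            # optional label / branch length
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            label = s[start:pos]
            if ":" in label:
                label = label.split(":")[0]
            if label and node.is_leaf:
                node.taxon = label
            return node

        tree = cls(parse())
        return tree

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.taxon)
            for c in node.children:
                new.add(rec(c))
            return new

        return Tree(rec(self.root))

    # -- traversal --------------------------------------------------------

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.taxon for n in self.leaves()]

    def iter_edges(self) -> Iterator[Node]:
        """Yield the child endpoint of every edge (all non-root nodes)."""
        for node in self.postorder():
            if node.parent is not None:
                yield node

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    # -- surgery ----------------------------------------------------------

    def insert_leaf_above(self, node: Node, taxon: str) -> Node:
        """Split the edge above ``node`` and hang a new leaf off the new node."""
        parent = node.parent
        if parent is None:
            raise ValueError("cannot insert above the root")
        mid = Node()
        leaf = Node(taxon)
        idx = parent.children.index(node)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add(node)
        mid.add(leaf)
        return leaf

    def prune(self, node: Node) -> Node:
        """Detach the subtree rooted at ``node``; suppress the degree-2 parent.

        Returns the detached subtree root (parentless).  The pruned node's
        parent must not be the root unless the root is binary, in which case
        the sibling becomes the new root.
        """
        parent = node.parent
        if parent is None:
            raise ValueError("cannot prune the root")
        parent.children.remove(node)
        node.parent = None
        if len(parent.children) == 1:
            only = parent.children[0]
            grand = parent.parent
            if grand is None:
                only.parent = None
                self.root = only
            else:
                idx = grand.children.index(parent)
                grand.children[idx] = only
                only.parent = grand
        return node

    def reroot_above(self, node: Node) -> None:
        """Re-root the tree so the root sits on the edge above ``node``.

        Valid only for trees whose current root is binary (degree-2 point on
        an edge); the operation preserves the underlying unrooted topology.
        """
        if node.parent is None:
            return
        if node.parent is self.root and len(self.root.children) == 2:
            return
        # collect path from node up to root
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        old_root = path[-1]
        # detach node, then flip parent pointers along the path
        new_root = Node()
        parent = node.parent
        parent.children.remove(node)
        new_root.add(node)
        # walk upward: each former parent becomes a child
        prev = new_root
        current = parent
        while current is not None:
            nxt = current.parent
            if nxt is not None:
                nxt.children.remove(current)
            current.parent = None
            prev.add(current)
            prev = current
            current = nxt
        # suppress the old (now degree-1/2) root if it became redundant
        self._suppress_unary(old_root)
        self.root = new_root

    def _suppress_unary(self, node: Node) -> None:
        if len(node.children) == 1 and node.parent is not None:
            only = node.children[0]
            idx = node.parent.children.index(node)
            node.parent.children[idx] = only
            only.parent = node.parent
        elif len(node.children) == 1 and node.parent is None:  # pragma: no cover
            only = node.children[0]
            only.parent = None
            self.root = only

    # -- canonical form ---------------------------------------------------

    def newick(self, label: Optional[Callable[[Node], str]] = None) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                return node.taxon or ""
            inner = ",".join(rec(c) for c in node.children)
            extra = label(node) if label else ""
            return f"({inner}){extra}"

        return rec(self.root) + ";"

    def canonical_newick(self) -> str:
        """Rooted canonical form: children sorted by their smallest leaf."""

        def rec(node: Node) -> str:
            if node.is_leaf:
                return node.taxon or ""
            parts = sorted(rec(c) for c in node.children)
            return "(" + ",".join(parts) + ")"

        return rec(self.root) + ";"

    def unrooted_key(self) -> str:
        """Canonical identifier of the underlying unrooted topology."""
        tree = self.copy()
        first = min(tree.leaf_labels())
        target = next(n for n in tree.leaves() if n.taxon == first)
        tree.reroot_above(target)
        return tree.canonical_newick()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.newick()})"


def star_tree(taxa: list[str]) -> Tree:
    root = Node()
    for t in taxa:
        root.add(Node(t))
    return Tree(root)


def cherry(a: str, b: str) -> Tree:
    root = Node()
    root.add(Node(a))
    root.add(Node(b))
    return Tree(root)
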