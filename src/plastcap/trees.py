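"""Rooted tree data model, newick I/O, pruning, scaling, and split extraction.

Branch lengths on species trees are interpreted as coalescent units
(2Ne generations of the diploid nuclear reference population).  Internal
node labels (e.g. bootstrap support) are parsed and preserved but never
used by any downstream computation.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "RootedTree",
    "Split",
    "NewickParseError",
    "TreeError",
    "parse_newick",
    "parse_newick_file",
    "write_newick",
    "prune_to_taxa",
    "scale_branch_lengths",
    "nontrivial_splits",
]


class TreeError(ValueError):
    """Structural problem with a tree or an operation on it."""


class NewickParseError(TreeError):
    """Malformed newick input; message names the offending position."""


class Node:
    """A node of a rooted tree.

    ``label`` is the leaf label for leaves and an optional support/label
    string for internal nodes.  ``length`` is the length of the edge above
    the node (``None`` for the root, and for edges with no length in the
    source newick — recorded as missing, not zero).
    """

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.parent: Node | None = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<Node {kind} label={self.label!r} length={self.length!r}>"


class RootedTree:
    """Leaf-labelled rooted tree with non-negative branch lengths.

    Invariants (enforced by :meth:`validate`, called on construction):
    exactly one root; unique non-empty leaf labels; at least one leaf;
    all present edge lengths >= 0.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- iteration -----------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def label_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- checks --------------------------------------------------------

    def validate(self) -> None:
        if self.root.parent is not None:
            raise TreeError("root must not have a parent")
        labels: list[str] = []
        for node in self.preorder():
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("inconsistent parent link")
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf with empty label")
                labels.append(node.label)
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative edge length {node.length}")
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {', '.join(dupes)}")

    def has_all_lengths(self) -> bool:
        return all(n.length is not None for n in self.preorder() if n.parent is not None)

    def is_bifurcating(self) -> bool:
        return all(len(n.children) == 2 for n in self.preorder() if not n.is_leaf)

    def depth(self) -> float:
        """Maximum root-to-leaf path length. Missing lengths count as 0."""
        best = 0.0
        stack = [(self.root, 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf:
                best = max(best, d)
            for c in node.children:
                stack.append((c, d + (c.length or 0.0)))
        return best

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []
        stack = [(self.root, 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf:
                depths.append(d)
            for c in node.children:
                stack.append((c, d + (c.length or 0.0)))
        return max(depths) - min(depths) <= tol

    def copy(self) -> "RootedTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return RootedTree(clone(self.root), validate=False)

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise TreeError(f"no leaf labelled {label!r}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RootedTree n_leaves={self.n_leaves}>"


# ---------------------------------------------------------------------
# Splits


class Split:
    """A bipartition of a taxon set, canonicalized so that a split and
    its complement compare equal.

    The stored block is the side containing the lexicographically
    smallest taxon label.
    """

    __slots__ = ("taxa", "block")

    def __init__(self, taxa: Iterable[str], block: Iterable[str]):
        taxa = frozenset(taxa)
        block = frozenset(block)
        if not block <= taxa:
            raise TreeError("split block is not a subset of the taxon set")
        if len(block) == 0 or len(block) == len(taxa):
            raise TreeError("split blocks must both be non-empty")
        if min(taxa) not in block:
            block = taxa - block
        self.taxa = taxa
        self.block = block

    @property
    def complement(self) -> frozenset[str]:
        return self.taxa - self.block

    @property
    def sizes(self) -> tuple[int, int]:
        a = len(self.block)
        return a, len(self.taxa) - a

    @property
    def is_nontrivial(self) -> bool:
        a, b = self.sizes
        return a >= 2 and b >= 2

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.taxa)), tuple(sorted(self.block)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Split):
            return NotImplemented
        return self.taxa == other.taxa and self.block == other.block

    def __hash__(self) -> int:
        return hash((self.taxa, self.block))

    def __repr__(self) -> str:
        a = ",".join(sorted(self.block))
        b = ",".join(sorted(self.complement))
        return f"Split({a}|{b})"


# ---------------------------------------------------------------------
# Newick I/O


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label, dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # a root edge length carries no information here
    return RootedTree(root)


def parse_newick(text: str) -> RootedTree:
    """Parse a single newick statement into a :class:`RootedTree`.

    Internal node labels (e.g. bootstrap values) are preserved.  Raises
    :class:`NewickParseError` (naming the offending position) on
    unbalanced parentheses, duplicate leaf labels, or empty input.
    """
    if not text or not text.strip():
        raise NewickParseError("empty newick input (position 0)")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy error messages carry line/column
        raise NewickParseError(str(exc)) from exc
    return _from_dendropy(dtree)


def parse_newick_file(path: str) -> list[RootedTree]:
    """Parse a newick file with one tree statement per line."""
    trees = []
    with io.open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    if not trees:
        raise NewickParseError(f"no trees found in {path}")
    return trees


def _min_leaf(node: Node, cache: dict) -> str:
    if id(node) in cache:
        return cache[id(node)]
    if node.is_leaf:
        val = node.label
    else:
        val = min(_min_leaf(c, cache) for c in node.children)
    cache[id(node)] = val
    return val


def _fmt_length(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: RootedTree) -> str:
    """Serialize deterministically: children ordered by smallest
    descendant leaf label, so output files are diffable."""
    cache: dict = {}

    def emit(node: Node) -> str:
        if node.is_leaf:
            s = node.label
        else:
            kids = sorted(node.children, key=lambda c: _min_leaf(c, cache))
            s = "(" + ",".join(emit(c) for c in kids) + ")"
            if node.label:
                s += str(node.label)
        if node.length is not None and node.parent is not None:
            s += ":" + _fmt_length(node.length)
        return s

    return emit(tree.root) + ";"


def write_newick_file(trees: Iterable[RootedTree], path: str) -> None:
    with io.open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------
# Operations


def prune_to_taxa(tree: RootedTree, keep: Iterable[str]) -> RootedTree:
    """Restrict a tree to ``keep`` ∩ leaves, suppressing unifurcations
    (edge lengths summed) and returning the root of the induced subtree.

    Leaf-to-leaf path lengths among retained taxa are conserved.
    """
    keep = frozenset(keep)
    shared = keep & tree.label_set()
    if not shared:
        raise TreeError("no shared taxa")
    t = tree.copy()

    # drop unwanted leaves, cascading removal of emptied internals
    for leaf in t.leaves():
        if leaf.label in shared:
            continue
        node = leaf
        while node.parent is not None:
            parent = node.parent
            parent.children.remove(node)
            node.parent = None
            if parent.children:
                break
            node = parent

    # suppress unifurcations below the root
    for node in list(t.postorder()):
        if node.parent is not None and len(node.children) == 1:
            child = node.children[0]
            if node.length is None and child.length is None:
                merged = None
            else:
                merged = (node.length or 0.0) + (child.length or 0.0)
            child.length = merged
            parent = node.parent
            parent.children[parent.children.index(node)] = child
            child.parent = parent

    # descend past any single-child chain at the root
    root = t.root
    while len(root.children) == 1:
        root = root.children[0]
    root.parent = None
    root.length = None
    return RootedTree(root)


def scale_branch_lengths(tree: RootedTree, factor: float) -> RootedTree:
    """Multiply every edge length by ``factor`` (> 0); topology unchanged.

    Raises if any non-root edge length is missing.
    """
    if not factor > 0:
        raise TreeError(f"scale factor must be positive, got {factor}")
    t = tree.copy()
    for node in t.preorder():
        if node.parent is None:
            continue
        if node.length is None:
            raise TreeError("cannot scale a tree with missing edge lengths")
        node.length *= factor
    return t


def nontrivial_splits(tree: RootedTree) -> frozenset[Split]:
    """One canonical :class:`Split` per internal edge of the unrooted
    version of the tree.  A fully resolved unrooted tree on n leaves
    yields exactly n - 3 splits; a star tree yields none.  Invariant to
    root placement.
    """
    taxa = tree.label_set()
    n = len(taxa)
    if n < 4:
        return frozenset()
    splits: set[Split] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is not None:
            blk = below[id(node)]
            if 2 <= len(blk) <= n - 2:
                splits.add(Split(taxa, blk))
    return frozenset(splits)
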