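import itertools

import numpy as np
import pytest

from plastcap.trees import Node, RootedTree


def random_binary_tree(n, rng, prefix="t", with_lengths=True):
    """Random binary topology via sequential pair joining, random
    U(0.1, 2) edge lengths."""
    nodes = [Node(f"{prefix}{i:02d}") for i in range(1, n + 1)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = RootedTree(nodes[0])
    if with_lengths:
        for node in tree.preorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.1, 2.0))
    return tree


def enumerate_unrooted_binary_trees(labels):
    """All unrooted binary topologies on the given labels, represented
    as rooted trees with a trifurcating root (edge lengths 1.0).
    Counts: 3 for n=4, 15 for n=5, 105 for n=6."""
    labels = list(labels)
    assert len(labels) >= 3

    def clone(node):
        new = Node(node.label, node.length)
        for c in node.children:
            new.add_child(clone(c))
        return new

    root = Node()
    for lab in labels[:3]:
        root.add_child(Node(lab, 1.0))
    trees = [root]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            edges = [n for n in _preorder(t) if n.parent is not None]
            for k in range(len(edges)):
                t2 = clone(t)
                target = [n for n in _preorder(t2) if n.parent is not None][k]
                parent = target.parent
                mid = Node(length=1.0)
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add_child(target)
                target.length = 1.0
                mid.add_child(Node(lab, 1.0))
                nxt.append(t2)
        trees = nxt
    return [RootedTree(t) for t in trees]


def _preorder(node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def brute_force_shared_info(splits1, splits2, mci_fn):
    """Maximum total MCI over all one-to-one matchings, by exhaustive
    permutation — the independent oracle for the assignment step."""
    small, large = sorted((list(splits1), list(splits2)), key=len)
    if not small:
        return 0.0
    best = 0.0
    for perm in itertools.permutations(range(len(large)), len(small)):
        total = sum(mci_fn(small[i], large[j]) for i, j in enumerate(perm))
        best = max(best, total)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
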