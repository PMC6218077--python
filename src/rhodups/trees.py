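"""Small helpers on top of dendropy trees.

All trees in this package are dendropy :class:`~dendropy.Tree` objects.
Functions here cover the recurring plumbing: Newick round-trips with a
shared TaxonNamespace, unrooted bipartition sets restricted to a taxon
subset, constraint compatibility, and deterministic random resolution of
polytomies.
"""
from __future__ import annotations

from typing import Iterable, Optional, Set, FrozenSet

import dendropy
import numpy as np

__all__ = [
    "read_tree",
    "write_tree",
    "leaf_labels",
    "bipartitions",
    "is_compatible",
    "random_resolve",
    "rf_distance",
]


def read_tree(source: str, namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
    """Read a Newick tree from a string or a file path."""
    kwargs = dict(schema="newick", preserve_underscores=True)
    if namespace is not None:
        kwargs["taxon_namespace"] = namespace
    if "(" in source:
        return dendropy.Tree.get(data=source, **kwargs)
    return dendropy.Tree.get(path=source, **kwargs)


def write_tree(tree: dendropy.Tree, path: Optional[str] = None) -> str:
    s = tree.as_string(schema="newick", unquoted_underscores=True,
                       suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def leaf_labels(tree: dendropy.Tree) -> Set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree,
                 restrict_to: Optional[Iterable[str]] = None) -> Set[FrozenSet[str]]:
    """Non-trivial unrooted bipartitions, each as the frozenset of labels on
    the side *not* containing the lexicographically smallest shared label.

    When ``restrict_to`` is given, every bipartition is first restricted to
    that label set; restrictions that become trivial (one side with < 2
    labels) are dropped.
    """
    labels = leaf_labels(tree)
    if restrict_to is not None:
        labels = labels & set(restrict_to)
    if len(labels) < 4:
        return set()
    anchor = min(labels)
    out: Set[FrozenSet[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()} & labels
        if anchor in side:
            side = labels - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(frozenset(side))
    return out


def is_compatible(tree: dendropy.Tree, constraint: dendropy.Tree) -> bool:
    """True iff every non-trivial bipartition induced by ``constraint``
    (restricted to the taxa shared with ``tree``) occurs in ``tree``.

    A multifurcating constraint induces only the bipartitions of its resolved
    edges, so a star constraint is compatible with everything.
    """
    shared = leaf_labels(tree) & leaf_labels(constraint)
    if len(shared) < 4:
        return True
    have = bipartitions(tree, restrict_to=shared)
    need = bipartitions(constraint, restrict_to=shared)
    return need <= have


def random_resolve(tree: dendropy.Tree, rng: np.random.Generator,
                   default_edge_length: float = 0.01) -> dendropy.Tree:
    """Resolve all polytomies in place with seeded random binary splits."""
    for node in list(tree.preorder_node_iter()):
        while len(node.child_nodes()) > 2:
            kids = node.child_nodes()
            i, j = sorted(rng.choice(len(kids), size=2, replace=False))
            a, b = kids[i], kids[j]
            node.remove_child(a)
            node.remove_child(b)
            joint = dendropy.Node()
            joint.edge.length = default_edge_length
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
    return tree


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric bipartition difference)."""
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)
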