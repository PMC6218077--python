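"""Parsimony ancestral-state reconstruction of opsin-gene characters.

Characters are unordered and equally weighted (an ordered flag exists for
the copy-number character but is off by default), and missing data ``?``
is a leaf compatible with every state, which is exactly why parsimony was
the tool of choice for these patchily-known genomic characters.  The
implementation is Sankoff dynamic programming, which coincides with Fitch
counting for unordered states, handles multifurcations natively, and
yields the full most-parsimonious (MPR) state set per node via a second,
root-to-tip pass.

``count_gains`` answers questions of the form "how many independent
1 -> 2 copy-number gains happened inside the Teleostei?": it reports the
minimum number of from->to transitions on branches inside a clade over
all most-parsimonious reconstructions, via a lexicographic two-part cost
(changes first, focal gains second).

A small backbone phylogeny of jawed vertebrates and the matching
character matrix (presence of the pineal exo-rhodopsin gene, presence of
the ancestral rh1 introns, and intron-less rh1 copy number) ship as
packaged fixtures; taxa whose states the underlying survey leaves open
are coded ``?``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .trees import read_tree

__all__ = [
    "CharacterMatrix",
    "AcrResult",
    "fitch_acr",
    "count_gains",
    "backbone_tree",
    "opsin_character_matrix",
]

_BIG = 10 ** 6   # lexicographic weight: changes dominate focal-gain count
MISSING = "?"


class CharacterMatrix:
    """Taxa x characters table of discrete states ('?' = missing)."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.astype(str)

    @classmethod
    def from_tsv(cls, path) -> "CharacterMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                               keep_default_na=False))

    @property
    def taxa(self) -> List[str]:
        return list(self.table.index)

    @property
    def characters(self) -> List[str]:
        return list(self.table.columns)

    def column(self, character: str) -> Dict[str, str]:
        return dict(self.table[character])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass
class AcrResult:
    """Most-parsimonious reconstruction of one character."""
    tree: dendropy.Tree
    character: Dict[str, str]
    states: Tuple[str, ...]
    min_changes: int
    node_states: Dict[int, FrozenSet[str]]     # id(node) -> MPR state set
    ordered: bool = False

    def leaf_state_sets(self) -> Dict[str, FrozenSet[str]]:
        return {lf.taxon.label: self.node_states[id(lf)]
                for lf in self.tree.leaf_node_iter()}

    def annotated_newick(self) -> str:
        clone = dendropy.Tree(self.tree)
        for node, orig in zip(clone.preorder_node_iter(),
                              self.tree.preorder_node_iter()):
            ss = "/".join(sorted(self.node_states[id(orig)]))
            node.annotations.add_new("states", ss)
        return clone.as_string(schema="newick", unquoted_underscores=True,
                               suppress_annotations=False)


def _leaf_cost(state_label: str, states: Sequence[str]) -> np.ndarray:
    if state_label == MISSING:
        return np.zeros(len(states))
    if state_label not in states:
        raise ValueError(f"unknown state {state_label!r}")
    cost = np.full(len(states), np.inf)
    cost[states.index(state_label)] = 0.0
    return cost


def _step_matrix(states: Sequence[str], ordered: bool) -> np.ndarray:
    k = len(states)
    if not ordered:
        return 1.0 - np.eye(k)
    vals = np.array([float(s) for s in states])
    return np.abs(vals[:, None] - vals[None, :])


def fitch_acr(tree: dendropy.Tree, character: Dict[str, str],
              states: Optional[Sequence[str]] = None,
              ordered: bool = False) -> AcrResult:
    """Minimum-change reconstruction with full MPR state sets per node.

    ``character`` maps leaf labels to state strings ('?' allowed).  The
    state space defaults to the observed states sorted lexicographically.
    Multifurcations are handled natively by the dynamic programme.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = leaves - set(character)
    if missing:
        raise ValueError(f"no character state for taxa: {sorted(missing)}")
    if states is None:
        states = sorted({s for s in character.values() if s != MISSING})
    states = tuple(states)
    if not states:
        raise ValueError("character has no observed states")
    step = _step_matrix(states, ordered)

    up: Dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            up[id(node)] = _leaf_cost(character[node.taxon.label], states)
        else:
            total = np.zeros(len(states))
            for c in node.child_nodes():
                total += (step + up[id(c)][None, :]).min(axis=1)
            up[id(node)] = total
    root = tree.seed_node
    min_changes = float(up[id(root)].min())

    # downward pass: cost of the rest of the tree given each node state
    down: Dict[int, np.ndarray] = {id(root): np.zeros(len(states))}
    for node in tree.preorder_node_iter():
        for c in node.child_nodes():
            sib = np.zeros(len(states))
            for o in node.child_nodes():
                if o is not c:
                    sib += (step + up[id(o)][None, :]).min(axis=1)
            parent_tot = down[id(node)] + sib
            down[id(c)] = (step.T + parent_tot[None, :]).min(axis=1)

    node_states: Dict[int, FrozenSet[str]] = {}
    for node in tree.preorder_node_iter():
        total = up[id(node)] + down[id(node)]
        best = total.min()
        node_states[id(node)] = frozenset(
            s for s, t in zip(states, total) if t <= best + 1e-9)
        if not node_states[id(node)]:
            raise AssertionError("empty MPR state set (internal error)")
    return AcrResult(tree, dict(character), states, int(round(min_changes)),
                     node_states, ordered)


def count_gains(acr: AcrResult, from_state: str, to_state: str,
                clade_root: Optional[str] = None) -> int:
    """Minimum number of from->to transitions inside a clade over all MPRs.

    ``clade_root`` is a node label (or leaf label); transitions are counted
    on branches whose child lies strictly inside that clade.  With ``None``
    the whole tree counts.  The answer is computed by a Sankoff pass whose
    edge cost is ``changes * 1e6 + focal_gain``, so the gain count is
    minimised subject to the reconstruction staying most parsimonious.
    """
    tree, states, step0 = acr.tree, acr.states, _step_matrix(acr.states, acr.ordered)
    if from_state not in states or to_state not in states:
        return 0
    target = None
    if clade_root is not None:
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.is_leaf() else node.label
            if label == clade_root:
                target = node
                break
        if target is None:
            raise ValueError(f"clade root {clade_root!r} not found")
        # a branch lies inside the clade iff its child node does; the branch
        # leading into the clade root itself is outside
        inside = {id(n) for n in target.preorder_iter()} - {id(target)}
    else:
        inside = {id(n) for n in tree.preorder_node_iter()
                  if n.parent_node is not None}
    i_from, i_to = states.index(from_state), states.index(to_state)

    def edge_cost(child) -> np.ndarray:
        cost = step0 * _BIG
        if id(child) in inside:
            cost = cost.copy()
            cost[i_from, i_to] += 1.0
        return cost

    up: Dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            up[id(node)] = _leaf_cost(acr.character[node.taxon.label], states)
        else:
            total = np.zeros(len(states))
            for c in node.child_nodes():
                total += (edge_cost(c) + up[id(c)][None, :]).min(axis=1)
            up[id(node)] = total
    best = up[id(tree.seed_node)].min()
    return int(round(best % _BIG))


# -- packaged fixtures --------------------------------------------------

def backbone_tree() -> dendropy.Tree:
    """Simplified rooted phylogeny of jawed vertebrates (named clades)."""
    data = resources.files("rhodups.data").joinpath("jawed_vertebrates.nwk")
    return read_tree(data.read_text())


def opsin_character_matrix() -> CharacterMatrix:
    """Presence of exo-rh1, rh1 introns, and intron-less rh1 copy number."""
    data = resources.files("rhodups.data").joinpath("opsin_characters.tsv")
    import io
    return CharacterMatrix(pd.read_csv(io.StringIO(data.read_text()), sep="\t",
                                       index_col=0, dtype=str,
                                       keep_default_na=False))
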