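"""Maximum-likelihood topology search with constraints and bootstrap.

The search is a multi-start NNI hill climb: each start builds a
constraint-compatible random-addition tree (polytomies of the constraint
resolved at random, unconstrained taxa inserted on random edges), fits
branch lengths, then repeatedly scans all nearest-neighbour interchanges,
scoring each candidate after a cheap local branch-length pass and fully
re-optimising whenever a move improves the likelihood.  Moves that would
violate the constraint are never accepted, so the returned tree is always
constraint-compatible.  Ties between equally likely topologies break on
the lexicographic order of their Newick strings, which makes runs with a
fixed seed reproducible bit for bit.

Bootstrap support resamples alignment columns with replacement at the
original length, re-searches every pseudo-replicate (single start, seeded
from the replicate index) and reports the percentage of replicates
containing each bipartition of the best tree.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .alignment import MultipleAlignment
from .likelihood import TreeLikelihood
from .substmodel import GTRGamma
from .trees import bipartitions, is_compatible, leaf_labels, random_resolve

__all__ = ["SearchResult", "ml_search", "bootstrap_support", "BootstrapResult",
           "support_display_class"]

_DEFAULT_BL = 0.05


@dataclass
class SearchResult:
    """Best tree found by :func:`ml_search` with its fitted model."""
    tree: dendropy.Tree
    loglik: float
    model: GTRGamma
    n_moves_evaluated: int = 0

    def site_log_likelihoods(self) -> np.ndarray:
        return self._engine.site_log_likelihoods(self.model)

    _engine: Optional[TreeLikelihood] = field(default=None, repr=False)


def _start_tree(taxa: Sequence[str], constraint: Optional[dendropy.Tree],
                rng: np.random.Generator) -> dendropy.Tree:
    """Random-addition starting tree honouring the constraint.

    Taxa outside the constraint never create bipartitions among constraint
    taxa, so inserting them on arbitrary edges preserves compatibility.
    """
    ns = dendropy.TaxonNamespace()
    taxa = list(taxa)
    if constraint is not None:
        shared = sorted(set(taxa) & leaf_labels(constraint))
        base = dendropy.Tree(constraint)
        base.retain_taxa_with_labels(shared)
        # re-home the constraint skeleton onto a fresh namespace
        skeleton = base.as_string(schema="newick")
        tree = dendropy.Tree.get(data=skeleton, schema="newick",
                                 taxon_namespace=ns, preserve_underscores=True)
        random_resolve(tree, rng, default_edge_length=_DEFAULT_BL)
        remaining = [t for t in taxa if t not in set(shared)]
    else:
        tree = dendropy.Tree(taxon_namespace=ns)
        order = list(rng.permutation(len(taxa)))
        first = [taxa[i] for i in order[:3]]
        for lab in first:
            node = dendropy.Node()
            node.taxon = ns.new_taxon(label=lab)
            node.edge.length = _DEFAULT_BL
            tree.seed_node.add_child(node)
        remaining = [taxa[i] for i in order[3:]]
        random_resolve(tree, rng, default_edge_length=_DEFAULT_BL)
    order = list(rng.permutation(len(remaining)))
    for i in order:
        lab = remaining[i]
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None]
        edge = edges[int(rng.integers(len(edges)))]
        # split the edge and hang the new leaf off the midpoint
        head = edge.head_node
        parent = head.parent_node
        mid = dendropy.Node()
        parent.remove_child(head)
        parent.add_child(mid)
        mid.edge.length = (edge.length or _DEFAULT_BL) / 2
        head.edge.length = (edge.length or _DEFAULT_BL) / 2
        mid.add_child(head)
        leaf = dendropy.Node()
        leaf.taxon = ns.new_taxon(label=lab)
        leaf.edge.length = _DEFAULT_BL
        mid.add_child(leaf)
    for e in tree.preorder_edge_iter():
        if e.length is None:
            e.length = _DEFAULT_BL
    tree.suppress_unifurcations()
    return tree


def _nni_moves(tree: dendropy.Tree) -> List[Tuple[int, int]]:
    """All NNI moves as (postorder node index of v, child index) pairs."""
    moves = []
    for i, v in enumerate(tree.postorder_node_iter()):
        if v.is_leaf() or v.parent_node is None:
            continue
        siblings = [c for c in v.parent_node.child_nodes() if c is not v]
        if len(siblings) != 1:
            continue
        for ci in range(len(v.child_nodes())):
            moves.append((i, ci))
    return moves


def _apply_nni(tree: dendropy.Tree, move: Tuple[int, int]) -> List[dendropy.Node]:
    """Swap child ``ci`` of node ``v`` with v's sibling, in place.

    Returns the nodes whose incident branch lengths the move perturbs.
    """
    nodes = list(tree.postorder_node_iter())
    v = nodes[move[0]]
    u = v.parent_node
    s = [c for c in u.child_nodes() if c is not v][0]
    c = v.child_nodes()[move[1]]
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)
    touched = [v, s, c] + v.child_nodes()
    if u.parent_node is not None:
        touched.append(u)
    return touched


def _topology_key(tree: dendropy.Tree) -> str:
    clone = dendropy.Tree(tree)
    for e in clone.preorder_edge_iter():
        e.length = None
    clone.ladderize()
    return clone.as_string(schema="newick", unquoted_underscores=True)


def ml_search(aln: MultipleAlignment, model: GTRGamma,
              constraint: Optional[dendropy.Tree] = None,
              n_starts: int = 2, seed: int = 0,
              optimize_model: bool = False,
              start_tree: Optional[dendropy.Tree] = None,
              tol: float = 1e-4) -> SearchResult:
    """Multi-start constrained NNI hill climb; returns the best tree found.

    The reported log-likelihood is the full re-scored value of the returned
    tree.  ``optimize_model=True`` additionally fits the substitution model
    (on the starting tree and again on the final tree).
    """
    taxa = list(aln.ids)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa to search")
    if constraint is not None:
        extra = leaf_labels(constraint) - set(taxa)
        if extra:
            raise ValueError(f"constraint taxa absent from alignment: {sorted(extra)}")
    if start_tree is not None:
        n_starts = 1
    streams = np.random.SeedSequence(seed).spawn(max(n_starts, 1))
    best: Optional[Tuple[float, str, dendropy.Tree, GTRGamma]] = None
    n_eval = 0
    for stream in streams:
        rng = np.random.default_rng(stream)
        if start_tree is not None:
            skeleton = start_tree.as_string(schema="newick")
            tree = dendropy.Tree.get(data=skeleton, schema="newick",
                                     taxon_namespace=dendropy.TaxonNamespace(),
                                     preserve_underscores=True)
        else:
            tree = _start_tree(taxa, constraint, rng)
        engine = TreeLikelihood(tree, aln, model)
        fit = engine.fit(optimize="both" if optimize_model else "branch_lengths",
                         tol=tol)
        cur_model = fit.model
        cur_lnl = fit.loglik
        # never revisit a topology: convergence slack in the branch fits
        # could otherwise let marginal moves cycle indefinitely
        seen = {_topology_key(tree)}
        improved = True
        while improved:
            improved = False
            candidates = []
            for move in _nni_moves(tree):
                cand = dendropy.Tree(tree)
                touched = _apply_nni(cand, move)
                if constraint is not None and not is_compatible(cand, constraint):
                    continue
                key = _topology_key(cand)
                if key in seen:
                    continue
                cand_engine = TreeLikelihood(cand, aln, cur_model)
                local = [cand_engine._idx.index[id(n)] for n in touched
                         if n.parent_node is not None]
                lnl = cand_engine._optimize_branches(cur_model, edges=local,
                                                     xatol=1e-5)
                n_eval += 1
                if lnl > cur_lnl + 1e-6:
                    candidates.append((lnl, key, cand))
            if candidates:
                candidates.sort(key=lambda t: (-t[0], t[1]))
                _, key, tree = candidates[0]
                seen.add(key)
                engine = TreeLikelihood(tree, aln, cur_model)
                fit = engine.fit(optimize="branch_lengths", tol=tol)
                cur_lnl = fit.loglik
                improved = True
        if optimize_model:
            fit = engine.fit(optimize="both", tol=tol)
            cur_model, cur_lnl = fit.model, fit.loglik
        key = _topology_key(tree)
        if best is None or cur_lnl > best[0] + 1e-9 or \
                (abs(cur_lnl - best[0]) <= 1e-9 and key < best[1]):
            best = (cur_lnl, key, tree, cur_model)
    lnl, _, tree, fitted = best
    result = SearchResult(tree, lnl, fitted, n_eval)
    result._engine = TreeLikelihood(tree, aln, fitted)
    return result


@dataclass
class BootstrapResult:
    """Best tree annotated with bootstrap support percentages."""
    tree: dendropy.Tree
    support: Dict[frozenset, float]             # bipartition -> % of replicates
    n_replicates: int
    flag: Optional[str] = None

    def support_table(self):
        import pandas as pd
        rows = [{"bipartition": "|".join(sorted(k)), "support_pct": v}
                for k, v in sorted(self.support.items(),
                                   key=lambda kv: -kv[1])]
        return pd.DataFrame(rows)


def bootstrap_support(aln: MultipleAlignment, model: GTRGamma, B: int,
                      seed: int = 0, n_starts: int = 1,
                      best: Optional[SearchResult] = None) -> BootstrapResult:
    """Nonparametric bootstrap support for the ML tree's bipartitions."""
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    if best is None:
        best = ml_search(aln, model, n_starts=n_starts, seed=seed,
                         optimize_model=False)
    target = bipartitions(best.tree)
    no_signal = bool((aln.matrix == aln.matrix[0]).all())
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for b in range(B):
        cols = rng.integers(0, aln.length, size=aln.length)
        mat = aln.matrix[:, cols]
        rep = MultipleAlignment(
            [(i, "".join(row)) for i, row in zip(aln.ids, mat)])
        res = ml_search(rep, model, n_starts=1, seed=int(rng.integers(2 ** 31)),
                        optimize_model=False, start_tree=best.tree)
        found = bipartitions(res.tree)
        for bp in target:
            if bp in found:
                counts[bp] += 1
    support = {bp: (0.0 if no_signal else 100.0 * c / B)
               for bp, c in counts.items()}
    out_tree = dendropy.Tree(best.tree)
    labels = leaf_labels(out_tree)
    anchor = min(labels)
    for node in out_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if anchor in side:
            side = labels - side
        key = frozenset(side)
        if key in support:
            node.label = f"{support[key]:.0f}"
    return BootstrapResult(out_tree, support, B,
                           flag="no_signal" if no_signal else None)


def support_display_class(support_pct: float) -> str:
    """Display class for a bootstrap percentage: strong support (>79%)
    renders black, moderate (60-79%) gray, and weaker values are hidden."""
    if support_pct > 79:
        return "black"
    if support_pct >= 60:
        return "gray"
    return "hidden"
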