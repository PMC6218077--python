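"""Gene-tree / species-tree reconciliation and the duplication/loss
hypotheses for teleost rhodopsin.

LCA reconciliation maps every gene-tree node to the species-tree last
common ancestor of its descendant species.  A node is a duplication iff it
maps to the same species node as one of its children; losses are counted
per gene-tree edge as the number of species-tree nodes skipped on the path
between the parent and child maps (plus the duplication-side absence when
the parent is a duplication).

Twelve scenarios for the history of the two intron-less rh1 copies in
teleosts are encoded as constraint topologies over seven gene lineages
(Elopomorpha rh1-dso / rh1-fwo, Hiodon rh1-1 / rh1-2, the remaining
osteoglossomorph rh1 group, and Clupeocephala rh1-A / rh1-B):

* scenario A (three duplications) - one in each major lineage (A1) or one
  on the teleost stem replacing the elopomorph-specific event (A2);
* scenario B (two duplications) - one in the osteoglossomorph+clupeocephalan
  ancestor combined with an elopomorph-stem event (B1/B2) or a teleost-stem
  event (B3/B4); or a teleost-stem event combined with a clupeocephalan-stem
  event (B5/B6);
* scenario C (one duplication) - a single teleost-stem (genome-duplication)
  event explaining both copies everywhere (C1-C4 differ in which observed
  lineage descends from which product).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .trees import read_tree, leaf_labels
from .alignment import MultipleAlignment
from .substmodel import GTRGamma

__all__ = [
    "ReconciliationResult",
    "HypothesisSpec",
    "lca_reconcile",
    "build_hypothesis_topologies",
    "lineage_species_tree",
    "expand_constraint",
    "evaluate_hypotheses",
    "orthology_placement",
    "HYPOTHESIS_IDS",
    "LINEAGE_TAGS",
]

LINEAGE_TAGS = ("Elops_dso", "Elops_fwo", "Hiodon_1", "Hiodon_2",
                "Osteo", "Clupeo_A", "Clupeo_B")

HYPOTHESIS_IDS = ("A1", "A2", "B1", "B2", "B3", "B4",
                  "B5", "B6", "C1", "C2", "C3", "C4")

# Rooted topologies over the seven lineage tags.  The root corresponds to
# the ancestral teleost copy; outgroup taxa attach outside these clades.
_HYPOTHESIS_NEWICK = {
    "A1": "((Elops_dso,Elops_fwo),((Hiodon_2,(Hiodon_1,Osteo)),(Clupeo_A,Clupeo_B)));",
    "A2": "(Elops_dso,(Elops_fwo,((Hiodon_2,(Hiodon_1,Osteo)),(Clupeo_A,Clupeo_B))));",
    "B1": "((Elops_dso,Elops_fwo),(((Hiodon_1,Osteo),Clupeo_A),(Hiodon_2,Clupeo_B)));",
    "B2": "((Elops_dso,Elops_fwo),(((Hiodon_1,Osteo),Clupeo_B),(Hiodon_2,Clupeo_A)));",
    "B3": "(Elops_dso,(Elops_fwo,(((Hiodon_1,Osteo),Clupeo_A),(Hiodon_2,Clupeo_B))));",
    "B4": "(Elops_fwo,(Elops_dso,(((Hiodon_1,Osteo),Clupeo_A),(Hiodon_2,Clupeo_B))));",
    "B5": "((Elops_fwo,Hiodon_2),(Elops_dso,((Hiodon_1,Osteo),(Clupeo_A,Clupeo_B))));",
    "B6": "((Elops_dso,Hiodon_2),(Elops_fwo,((Hiodon_1,Osteo),(Clupeo_A,Clupeo_B))));",
    "C1": "((Elops_dso,(Hiodon_2,Clupeo_A)),(Elops_fwo,((Hiodon_1,Osteo),Clupeo_B)));",
    "C2": "((Elops_dso,(Hiodon_2,Clupeo_B)),(Elops_fwo,((Hiodon_1,Osteo),Clupeo_A)));",
    "C3": "((Elops_fwo,(Hiodon_2,Clupeo_A)),(Elops_dso,((Hiodon_1,Osteo),Clupeo_B)));",
    "C4": "((Elops_fwo,(Hiodon_2,Clupeo_B)),(Elops_dso,((Hiodon_1,Osteo),Clupeo_A)));",
}

_DESCRIPTIONS = {
    "A1": "three lineage-specific duplications (Elopomorpha, Osteoglossomorpha, Clupeocephala)",
    "A2": "three duplications: teleost stem plus Osteoglossomorpha and Clupeocephala",
    "B1": "elopomorph-stem and osteoglossomorph+clupeocephalan duplications (rh1-A with rh1-1 group)",
    "B2": "elopomorph-stem and osteoglossomorph+clupeocephalan duplications (rh1-B with rh1-1 group)",
    "B3": "teleost-stem (dso side isolated) and osteoglossomorph+clupeocephalan duplications",
    "B4": "teleost-stem (fwo side isolated) and osteoglossomorph+clupeocephalan duplications",
    "B5": "teleost-stem and clupeocephalan-stem duplications; old copy kept as fwo and rh1-2",
    "B6": "teleost-stem and clupeocephalan-stem duplications; old copy kept as dso and rh1-2",
    "C1": "single teleost-stem duplication; rh1-2/rh1-A with dso, rh1-1/rh1-B with fwo",
    "C2": "single teleost-stem duplication; rh1-2/rh1-B with dso, rh1-1/rh1-A with fwo",
    "C3": "single teleost-stem duplication; rh1-2/rh1-A with fwo, rh1-1/rh1-B with dso",
    "C4": "single teleost-stem duplication; rh1-2/rh1-B with fwo, rh1-1/rh1-A with dso",
}

#: species lineage carrying each gene lineage, on the lineage-level species tree
TAG_SPECIES = {
    "Elops_dso": "Elopomorpha", "Elops_fwo": "Elopomorpha",
    "Hiodon_1": "Hiodon", "Hiodon_2": "Hiodon",
    "Osteo": "OtherOsteoglossomorpha",
    "Clupeo_A": "Clupeocephala", "Clupeo_B": "Clupeocephala",
}


def lineage_species_tree() -> dendropy.Tree:
    """Lineage-level teleost species tree used to score the hypotheses."""
    return read_tree(
        "(Elopomorpha,((Hiodon,OtherOsteoglossomorpha)Osteoglossomorpha,"
        "Clupeocephala)Osteoglossocephala)Teleostei;")


@dataclass
class ReconciliationResult:
    """LCA map with duplication and loss bookkeeping."""
    node_map: Dict[int, dendropy.Node]          # id(gene node) -> species node
    duplication_nodes: List[dendropy.Node]
    loss_count: int
    loss_locations: List[str]                   # species branch (child label)

    @property
    def duplication_count(self) -> int:
        return len(self.duplication_nodes)


def _species_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or "<unnamed>"


def lca_reconcile(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                  leaf_map: Dict[str, str],
                  restrict_to_sampled: bool = True) -> ReconciliationResult:
    """Reconcile a rooted gene tree against a rooted species tree.

    ``leaf_map`` sends gene-tree leaf labels to species labels.  With
    ``restrict_to_sampled`` (default) the species tree is first pruned to
    the species that actually carry gene copies, so absence of an entirely
    unsampled species is not billed as a loss.
    """
    for t in (gene_tree, species_tree):
        if len(t.seed_node.child_nodes()) > 2:
            raise ValueError("reconciliation needs rooted (bifurcating-root) trees")
    species = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    used = set(leaf_map.values())
    missing = used - species
    if missing:
        raise ValueError(f"species not in species tree: {sorted(missing)}")
    stree = species_tree
    if restrict_to_sampled and used != species:
        stree = dendropy.Tree(species_tree)
        stree.retain_taxa_with_labels(sorted(used))
    depth: Dict[int, int] = {}
    parent: Dict[int, Optional[dendropy.Node]] = {}
    sp_leaf: Dict[str, dendropy.Node] = {}
    for node in stree.preorder_node_iter():
        parent[id(node)] = node.parent_node
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1
        if node.is_leaf():
            sp_leaf[node.taxon.label] = node

    def lca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while depth[id(a)] > depth[id(b)]:
            a = parent[id(a)]
        while depth[id(b)] > depth[id(a)]:
            b = parent[id(b)]
        while a is not b:
            a, b = parent[id(a)], parent[id(b)]
        return a

    node_map: Dict[int, dendropy.Node] = {}
    dups: List[dendropy.Node] = []
    for g in gene_tree.postorder_node_iter():
        if g.is_leaf():
            label = g.taxon.label
            if label not in leaf_map:
                raise ValueError(f"gene leaf {label!r} missing from leaf map")
            node_map[id(g)] = sp_leaf[leaf_map[label]]
        else:
            m = None
            for c in g.child_nodes():
                m = node_map[id(c)] if m is None else lca(m, node_map[id(c)])
            node_map[id(g)] = m
            if any(node_map[id(c)] is m for c in g.child_nodes()):
                dups.append(g)

    dup_ids = {id(d) for d in dups}
    losses = 0
    locations: List[str] = []
    for g in gene_tree.preorder_node_iter():
        if g.parent_node is None:
            continue
        mu, mv = node_map[id(g.parent_node)], node_map[id(g)]
        start_at_parent_map = id(g.parent_node) in dup_ids
        # walk from mv up to mu; every node passed strictly between them (and
        # mu itself after a duplication) sheds the sibling branch as a loss
        walk = mv
        path: List[dendropy.Node] = []
        while walk is not mu:
            path.append(walk)
            walk = parent[id(walk)]
        stations = path[1:] + ([mu] if start_at_parent_map and mv is not mu else [])
        prev = {id(p): c for c, p in zip(path, path[1:] + [mu])}
        for s in stations:
            for child in s.child_nodes():
                if id(child) != id(prev.get(id(s))):
                    losses += 1
                    locations.append(_species_label(child))
    return ReconciliationResult(node_map, dups, losses, sorted(locations))


@dataclass
class HypothesisSpec:
    """One duplication/loss scenario as a lineage-level constraint."""
    id: str
    constraint: dendropy.Tree                   # rooted, over the lineage tags
    expected_D: int
    description: str = ""

    def representative_reconciliation(self) -> ReconciliationResult:
        """Reconcile the (resolved) lineage topology to the lineage species tree."""
        return lca_reconcile(self.constraint, lineage_species_tree(),
                             TAG_SPECIES, restrict_to_sampled=True)


def build_hypothesis_topologies(
        ids: Optional[Iterable[str]] = None) -> List[HypothesisSpec]:
    """Constraint topologies for the requested scenarios (default all 12)."""
    ids = list(ids) if ids is not None else list(HYPOTHESIS_IDS)
    specs = []
    for hid in ids:
        if hid not in _HYPOTHESIS_NEWICK:
            raise ValueError(f"unknown hypothesis id {hid!r}")
        tree = read_tree(_HYPOTHESIS_NEWICK[hid])
        specs.append(HypothesisSpec(hid, tree, {"A": 3, "B": 2, "C": 1}[hid[0]],
                                    _DESCRIPTIONS[hid]))
    return specs


def expand_constraint(spec: HypothesisSpec, tag_map: Dict[str, str],
                      free_taxa: Sequence[str] = ()) -> dendropy.Tree:
    """Taxon-level constraint: each lineage tag becomes an unresolved clade
    of the taxa carrying that tag; ``free_taxa`` (e.g. outgroups) join the
    root polytomy unconstrained.  Tags with no taxa are dropped.
    """
    by_tag: Dict[str, List[str]] = {}
    for taxon, tag in tag_map.items():
        by_tag.setdefault(tag, []).append(taxon)
    tree = dendropy.Tree(spec.constraint)
    tree.taxon_namespace = dendropy.TaxonNamespace()
    for leaf in list(tree.leaf_node_iter()):
        tag = leaf.taxon.label
        members = sorted(by_tag.get(tag, []))
        leaf.taxon = None
        if not members:
            parent = leaf.parent_node
            parent.remove_child(leaf)
            continue
        if len(members) == 1:
            leaf.taxon = tree.taxon_namespace.new_taxon(label=members[0])
        else:
            for m in members:
                child = dendropy.Node()
                child.taxon = tree.taxon_namespace.new_taxon(label=m)
                leaf.add_child(child)
    for extra in sorted(free_taxa):
        node = dendropy.Node()
        node.taxon = tree.taxon_namespace.new_taxon(label=extra)
        tree.seed_node.add_child(node)
    tree.suppress_unifurcations()
    return tree


@dataclass
class HypothesisReport:
    """Per-hypothesis ML scores and AU/np probabilities."""
    table: pd.DataFrame                         # hypothesis, minus_lnl, rank, au, np
    best_trees: Dict[str, dendropy.Tree]
    site_loglik: np.ndarray                     # n_sites x n_hypotheses
    alpha: float = 0.05

    def unrejected(self, by: str = "au") -> List[str]:
        col = {"au": "au", "np": "np"}[by]
        return list(self.table.loc[self.table[col] >= self.alpha, "hypothesis"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def evaluate_hypotheses(aln: MultipleAlignment, model: GTRGamma,
                        specs: Sequence[HypothesisSpec],
                        tag_map: Dict[str, str],
                        outgroup: Sequence[str] = (),
                        n_starts: int = 1, seed: int = 0,
                        optimize_model: str = "per_tree",
                        au_scales: Optional[Sequence[float]] = None,
                        au_B: int = 1000, alpha: float = 0.05) -> HypothesisReport:
    """Constrained ML search per scenario followed by the AU/np tests.

    ``tag_map`` assigns every ingroup alignment taxon its gene lineage tag;
    taxa listed in ``outgroup`` are left unconstrained.  With
    ``optimize_model='per_tree'`` the substitution model is re-optimised
    under every constraint; ``'shared'`` fits it once on the first
    constraint's tree and keeps it fixed afterwards.
    """
    from .search import ml_search
    from .topotests import au_test

    if optimize_model not in ("per_tree", "shared"):
        raise ValueError("optimize_model must be 'per_tree' or 'shared'")
    unknown = set(tag_map) - set(aln.ids)
    if unknown:
        raise ValueError(f"tagged taxa missing from alignment: {sorted(unknown)}")
    seeds = np.random.SeedSequence(seed).generate_state(len(specs))
    rows = []
    best_trees: Dict[str, dendropy.Tree] = {}
    site_cols = []
    shared_model = model
    for spec, s in zip(specs, seeds):
        constraint = expand_constraint(spec, tag_map, free_taxa=outgroup)
        res = ml_search(aln, shared_model, constraint=constraint,
                        n_starts=n_starts, seed=int(s % (2 ** 31)),
                        optimize_model=(optimize_model == "per_tree"
                                        or spec is specs[0]))
        if optimize_model == "shared":
            shared_model = res.model
        best_trees[spec.id] = res.tree
        site_cols.append(res.site_log_likelihoods())
        rows.append({"hypothesis": spec.id, "expected_D": spec.expected_D,
                     "minus_lnl": -res.loglik})
    matrix = np.column_stack(site_cols)
    au = au_test(matrix, tree_labels=[s.id for s in specs],
                 scales=au_scales, B=au_B, seed=seed)
    table = pd.DataFrame(rows).merge(
        au.table().rename(columns={"tree": "hypothesis"}), on="hypothesis")
    table["rank"] = table["minus_lnl"].rank(method="min").astype(int)
    table = table[["hypothesis", "expected_D", "minus_lnl", "rank", "au", "np"]]
    table = table.sort_values("rank", kind="stable").reset_index(drop=True)
    return HypothesisReport(table, best_trees, matrix, alpha=alpha)


def orthology_placement(aln: MultipleAlignment, model: GTRGamma,
                        query_taxa: Sequence[str],
                        candidates: Dict[str, Sequence[str]],
                        n_starts: int = 1, seed: int = 0,
                        optimize_model: bool = True) -> pd.DataFrame:
    """Force a query lineage to be sister to each candidate lineage in turn
    and rank the constrained ML scores (larger log-likelihood first).
    """
    from .search import ml_search
    if len(candidates) < 2:
        raise ValueError("need at least two candidate sister lineages")
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(len(candidates))
    for (name, taxa), s in zip(sorted(candidates.items()), seeds):
        ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=ns)
        clade = dendropy.Node()
        for t in sorted(set(query_taxa) | set(taxa)):
            node = dendropy.Node()
            node.taxon = ns.new_taxon(label=t)
            clade.add_child(node)
        tree.seed_node.add_child(clade)
        for t in sorted(set(aln.ids) - set(query_taxa) - set(taxa)):
            node = dendropy.Node()
            node.taxon = ns.new_taxon(label=t)
            tree.seed_node.add_child(node)
        res = ml_search(aln, model, constraint=tree, n_starts=n_starts,
                        seed=int(s % (2 ** 31)), optimize_model=optimize_model)
        rows.append({"candidate": name, "minus_lnl": -res.loglik})
    out = pd.DataFrame(rows).sort_values("minus_lnl", kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
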