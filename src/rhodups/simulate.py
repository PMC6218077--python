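"""Synthetic rhodopsin-like gene families: gene trees carrying known
duplication/loss events, and in-frame alignments evolved along them.

The generator starts from a (ultrametric, rooted) species tree of the
three major teleost lineages plus a cartilaginous-fish outgroup, picks a
duplication/loss scenario (the same A1..C4 catalogue used by the
hypothesis tests), and builds the gene tree by expanding the scenario's
lineage-level topology: each gene lineage is replaced by the species
subtree of the species that retain that copy.  Duplication nodes sit at
the midpoint of their species-tree branch; speciation nodes inherit the
species-tree node times, optionally rescaled by a rate multiplier.
The ground truth (duplication count, loss branches, leaf-to-species and
leaf-to-lineage maps) is recorded alongside, so reconciliation and
hypothesis evaluation can be validated without any downloads.

Sequences evolve site-independently under GTR+Gamma (root states drawn
from the stationary frequencies); an optional third-codon-position
frequency override introduces the compositional heterogeneity that
motivates RY recoding.  One stream of the user seed drives the gene-tree
stage and an independent stream the sequence stage, so either can be
varied alone.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .alignment import MultipleAlignment
from .reconcile import HYPOTHESIS_IDS, build_hypothesis_topologies, lca_reconcile
from .substmodel import GTRGamma
from .trees import read_tree

__all__ = [
    "GeneFamilyTruth",
    "SimulationModel",
    "default_species_tree",
    "compact_species_tree",
    "simulate_gene_tree",
    "simulate_alignment",
    "simulate_gene_family",
]

# -- species trees ------------------------------------------------------

_DEFAULT_SPECIES_NEWICK = """
((Scyliorhinus:0.35,Raja:0.35)Chondrichthyes:0.10,
 ((Elops:0.25,(Albula:0.19,(Anguilla:0.13,Synaphobranchus:0.13)Anguilloidei:0.06)
   :0.06)Elopomorpha:0.08,
  ((Hiodon:0.21,(Scleropages:0.13,Pantodon:0.13):0.08)Osteoglossomorpha:0.06,
   (Clupea:0.23,(Danio:0.15,Oryzias:0.15):0.08)Clupeocephala:0.04)
  Osteoglossocephala:0.06)Teleostei:0.12)Gnathostomata;
"""

_COMPACT_SPECIES_NEWICK = """
(Scyliorhinus:0.45,
 (Elops:0.33,((Hiodon:0.21,Pantodon:0.21)Osteoglossomorpha:0.06,Danio:0.27)
  Osteoglossocephala:0.06)Teleostei:0.12)Gnathostomata;
"""

#: species composing each lineage (intersected with the species tree in use)
_LINEAGE_SPECIES = {
    "Elopomorpha": ("Elops", "Albula", "Anguilla", "Synaphobranchus"),
    "Anguilliformes": ("Anguilla", "Synaphobranchus"),
    "Osteoglossomorpha": ("Hiodon", "Scleropages", "Pantodon"),
    "Hiodontidae": ("Hiodon",),
    "OtherOsteoglossomorpha": ("Scleropages", "Pantodon"),
    "Clupeocephala": ("Clupea", "Danio", "Oryzias"),
    "Otocephala": ("Clupea", "Danio"),
    "Outgroup": ("Scyliorhinus", "Raja"),
}

#: default species carrying each gene lineage; mirrors the observed
#: retention pattern (fwo kept by anguilliforms, rh1-2 only by Hiodon,
#: rh1-B only by otocephalans).  Falls back to the whole parent lineage
#: when a reduced species tree lacks the preferred carriers.
_TAG_SPAN = {
    "Elops_dso": ("Elopomorpha",),
    "Elops_fwo": ("Anguilliformes", "Elopomorpha"),
    "Hiodon_1": ("Hiodontidae",),
    "Hiodon_2": ("Hiodontidae",),
    "Osteo": ("OtherOsteoglossomorpha",),
    "Clupeo_A": ("Clupeocephala",),
    "Clupeo_B": ("Otocephala", "Clupeocephala"),
}

#: spans used with ``full_retention=True``: every paralog lineage keeps its
#: copy in every descendant species (no secondary losses beyond those the
#: scenario topology itself implies)
_FULL_SPAN = {
    "Elops_dso": ("Elopomorpha",),
    "Elops_fwo": ("Elopomorpha",),
    "Hiodon_1": ("Hiodontidae",),
    "Hiodon_2": ("Osteoglossomorpha",),
    "Osteo": ("OtherOsteoglossomorpha",),
    "Clupeo_A": ("Clupeocephala",),
    "Clupeo_B": ("Clupeocephala",),
}

#: short paralog labels used in gene-leaf names
TAG_LABEL = {
    "Elops_dso": "dso", "Elops_fwo": "fwo",
    "Hiodon_1": "rh1-1", "Hiodon_2": "rh1-2",
    "Osteo": "rh1", "Clupeo_A": "rh1-A", "Clupeo_B": "rh1-B",
}


def default_species_tree() -> dendropy.Tree:
    """12-species teleost + outgroup tree (branch lengths in subst/site)."""
    return read_tree(_DEFAULT_SPECIES_NEWICK.replace("\n", " "))


def compact_species_tree() -> dendropy.Tree:
    """One representative species per gene-lineage carrier; 6 species."""
    return read_tree(_COMPACT_SPECIES_NEWICK.replace("\n", " "))


# -- domain types -------------------------------------------------------

@dataclass
class GeneFamilyTruth:
    """Ground-truth record for one simulated gene family."""
    scenario_id: str
    gene_tree: dendropy.Tree
    events: List[Tuple[str, str]]              # (kind, species-tree branch)
    leaf_map: Dict[str, str]                   # gene leaf -> species
    tag_map: Dict[str, str]                    # gene leaf -> lineage tag
    seed: int
    duplication_count: int = 0
    loss_count: int = 0

    def outgroup_taxa(self) -> List[str]:
        return sorted(l for l, t in self.tag_map.items() if t == "outgroup")

    def to_json(self) -> str:
        payload = {
            "scenario_id": self.scenario_id,
            "seed": self.seed,
            "duplication_count": self.duplication_count,
            "loss_count": self.loss_count,
            "events": self.events,
            "leaf_map": self.leaf_map,
            "tag_map": self.tag_map,
            "gene_tree": self.gene_tree.as_string(schema="newick").strip(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SimulationModel:
    """Sequence-evolution settings for :func:`simulate_alignment`.

    ``third_position_freqs`` switches on lineage-specific compositional
    bias at silent sites: third codon positions evolve under the base
    model everywhere except along the terminal branches of the biased
    taxa, where the stationary frequencies are replaced by the override.
    By default the biased taxa are the clupeocephalan gene copies, the
    lineage where third-position GC bias is conspicuous in real data.
    Third positions additionally evolve ``third_position_rate`` times
    faster than the gene-wide average, reflecting the weaker constraint
    on silent sites.
    """
    model: GTRGamma = field(default_factory=lambda: GTRGamma(
        rates=(1.5, 4.0, 1.0, 1.2, 6.0, 1.0),
        freqs=(0.22, 0.28, 0.24, 0.26),
        alpha=0.5, ncat=4))
    site_count: int = 996
    third_position_freqs: Optional[Tuple[float, float, float, float]] = None
    third_position_bias_taxa: Optional[Tuple[str, ...]] = None
    third_position_rate: float = 3.0           # silent-site rate acceleration
    root_sequence: Optional[str] = None        # e.g. rhodopsin_root_sequence()

    def __post_init__(self):
        if self.site_count < 1:
            raise ValueError("site_count must be positive")
        if self.third_position_freqs is not None:
            if self.site_count % 3 != 0:
                raise ValueError("site_count must be divisible by 3 when a "
                                 "third-position override is used")
            # validates the override frequencies
            self.model.with_(freqs=tuple(self.third_position_freqs))
        if self.root_sequence is not None:
            if len(self.root_sequence) != self.site_count:
                raise ValueError("root_sequence length must equal site_count")
            if set(self.root_sequence.upper()) - set("ACGT"):
                raise ValueError("root_sequence must be unambiguous A/C/G/T")


# -- gene-tree construction --------------------------------------------

def _node_depths(tree: dendropy.Tree) -> Dict[int, float]:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[id(node)] = 0.0
        else:
            depths[id(node)] = depths[id(node.parent_node)] + (node.edge.length or 0.0)
    return depths


def _species_subtree(species_tree: dendropy.Tree,
                     keep: Sequence[str]) -> dendropy.Tree:
    sub = dendropy.Tree(species_tree)
    sub.retain_taxa_with_labels(sorted(keep))
    return sub


def _tag_span(tag: str, present: set, table=None) -> List[str]:
    for lineage in (table or _TAG_SPAN)[tag]:
        span = [s for s in _LINEAGE_SPECIES[lineage] if s in present]
        if span:
            return span
    return []


def simulate_gene_tree(species_tree: Optional[dendropy.Tree] = None,
                       scenario_id: str = "B6",
                       loss_spec: Optional[Sequence[Tuple[str, str]]] = None,
                       seed: int = 0,
                       rate_multiplier: float = 1.0,
                       full_retention: bool = False) -> GeneFamilyTruth:
    """Build the gene tree implied by a duplication/loss scenario.

    ``loss_spec`` lists additional losses as ``(lineage_tag, species_or_
    lineage_label)`` pairs: the named species (or every species of a named
    lineage) drop their copy of that gene lineage.  A specification that
    empties the whole family is rejected.

    By default each gene lineage spans the species in which the
    corresponding rhodopsin copy was actually observed (secondary losses
    included); ``full_retention=True`` instead keeps every copy in every
    descendant species, so only the losses implied by the scenario
    topology itself remain.
    """
    if scenario_id not in HYPOTHESIS_IDS:
        raise ValueError(f"unknown scenario id {scenario_id!r}")
    species_tree = species_tree if species_tree is not None else default_species_tree()
    present = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    span_table = _FULL_SPAN if full_retention else _TAG_SPAN
    spans: Dict[str, List[str]] = {
        t: _tag_span(t, present, span_table) for t in span_table}
    clades: Dict[str, set] = {sp: {sp} for sp in present}
    for lineage, members in _LINEAGE_SPECIES.items():
        clades.setdefault(lineage, set(members))
    for node in species_tree.preorder_node_iter():
        if not node.is_leaf() and node.label:
            clades.setdefault(node.label,
                              {lf.taxon.label for lf in node.leaf_iter()})
    for tag, where in (loss_spec or ()):
        if tag not in spans:
            raise ValueError(f"unknown gene lineage tag {tag!r}")
        if where not in clades:
            raise ValueError(f"unknown species or clade label {where!r}")
        spans[tag] = [s for s in spans[tag] if s not in clades[where]]
    spans = {t: s for t, s in spans.items() if s}
    if not spans:
        raise ValueError("loss specification removes every gene copy")

    spec = build_hypothesis_topologies([scenario_id])[0]
    template = dendropy.Tree(spec.constraint)
    # drop extinct lineages from the template
    kept = set(spans)
    template.retain_taxa_with_labels(sorted(kept & {lf.taxon.label
                                                    for lf in template.leaf_node_iter()}))
    if sum(len(s) for s in spans.values()) + len(_tag_span_out(present)) < 3:
        raise ValueError("fewer than 3 surviving gene copies")

    # assemble the gene tree: outgroup subtree + expanded template
    ns = dendropy.TaxonNamespace()
    gene = dendropy.Tree(taxon_namespace=ns)
    leaf_map: Dict[str, str] = {}
    tag_map: Dict[str, str] = {}

    def attach_span(parent: dendropy.Node, tag: str, span: List[str], label: str):
        sub = _species_subtree(species_tree, span)
        def copy(node, into):
            for child in node.child_nodes():
                fresh = dendropy.Node()
                if child.is_leaf():
                    name = f"{child.taxon.label}_{label}"
                    fresh.taxon = ns.new_taxon(label=name)
                    leaf_map[name] = child.taxon.label
                    tag_map[name] = tag
                fresh.label = None if child.is_leaf() else child.label
                into.add_child(fresh)
                copy(child, fresh)
        root = sub.seed_node
        if root.is_leaf():
            name = f"{root.taxon.label}_{label}"
            node = dendropy.Node()
            node.taxon = ns.new_taxon(label=name)
            leaf_map[name] = root.taxon.label
            tag_map[name] = tag
            parent.add_child(node)
        else:
            holder = dendropy.Node()
            parent.add_child(holder)
            copy(root, holder)

    out_span = _tag_span_out(present)
    if out_span:
        attach_span(gene.seed_node, "outgroup", out_span, "rh1")

    def expand(tnode, into):
        for child in tnode.child_nodes():
            if child.is_leaf():
                tag = child.taxon.label
                attach_span(into, tag, spans[tag], TAG_LABEL[tag])
            else:
                fresh = dendropy.Node()
                into.add_child(fresh)
                expand(child, fresh)

    ingroup_root = template.seed_node
    if ingroup_root.num_child_nodes() == 0:      # single surviving lineage
        tag = ingroup_root.taxon.label
        attach_span(gene.seed_node, tag, spans[tag], TAG_LABEL[tag])
    else:
        holder = dendropy.Node()
        gene.seed_node.add_child(holder)
        expand(ingroup_root, holder)
    gene.suppress_unifurcations()

    # time the gene tree by reconciliation onto the species tree
    recon = lca_reconcile(gene, species_tree, leaf_map,
                          restrict_to_sampled=False)
    depths = _node_depths(species_tree)
    dup_ids = {id(d) for d in recon.duplication_nodes}
    times: Dict[int, float] = {}
    for node in gene.preorder_node_iter():
        sp = recon.node_map[id(node)]
        if id(node) in dup_ids and sp.parent_node is not None:
            times[id(node)] = 0.5 * (depths[id(sp)] + depths[id(sp.parent_node)])
        else:
            times[id(node)] = depths[id(sp)]
        if node.parent_node is not None:
            dt = times[id(node)] - times[id(node.parent_node)]
            node.edge.length = max(dt, 0.0) * rate_multiplier

    events: List[Tuple[str, str]] = []
    for d in recon.duplication_nodes:
        sp = recon.node_map[id(d)]
        name = sp.taxon.label if sp.is_leaf() else (sp.label or "<unnamed>")
        events.append(("duplication", name))
    for loc in recon.loss_locations:
        events.append(("loss", loc))
    return GeneFamilyTruth(scenario_id, gene, events, leaf_map, tag_map,
                           seed, duplication_count=len(recon.duplication_nodes),
                           loss_count=recon.loss_count)


def _tag_span_out(present: set) -> List[str]:
    return [s for s in _LINEAGE_SPECIES["Outgroup"] if s in present]


# -- sequence simulation ------------------------------------------------

#: one common vertebrate codon per amino acid, for back-translation
_PREFERRED_CODON = {
    "A": "GCC", "R": "CGC", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}


def rhodopsin_root_sequence(site_count: int = 996) -> str:
    """Back-translate the bovine rhodopsin reference into a coding root.

    Using a real opsin as the ancestral sequence keeps simulated families
    recognisably rhodopsin-like, so the key-site machinery (which aligns
    translations against the bovine reference) works on simulator output.
    """
    from .keysites import bovine_reference
    nt = "".join(_PREFERRED_CODON[a] for a in bovine_reference())
    if site_count > len(nt):
        raise ValueError(f"site_count must be <= {len(nt)}")
    return nt[:site_count]


def _evolve(tree: dendropy.Tree, model: GTRGamma, n_sites: int,
            rng: np.random.Generator,
            biased_model: Optional[GTRGamma] = None,
            biased_taxa: Optional[Sequence[str]] = None,
            root_states: Optional[np.ndarray] = None
            ) -> Dict[str, np.ndarray]:
    """Site-independent GTR+Gamma simulation; returns state indices (0..3).

    When a ``biased_model`` and ``biased_taxa`` are given, every maximal
    clade whose leaves all belong to the biased set is re-equilibrated:
    its root states are redrawn from the biased stationary frequencies and
    its edges evolve under the biased model, emulating a lineage that has
    reached its own compositional equilibrium.
    """
    pi = np.asarray(model.freqs)
    cat_rates = model.category_rates
    cats = rng.integers(0, len(cat_rates), size=n_sites)
    biased_set = set(biased_taxa or ())
    in_biased: Dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            in_biased[id(node)] = node.taxon.label in biased_set
        else:
            in_biased[id(node)] = all(in_biased[id(c)] for c in node.child_nodes())
    states: Dict[int, np.ndarray] = {}
    root = tree.seed_node
    if root_states is not None:
        states[id(root)] = np.asarray(root_states, dtype=int)
    elif in_biased[id(root)] and biased_model is not None:
        states[id(root)] = rng.choice(4, size=n_sites,
                                      p=np.asarray(biased_model.freqs))
    else:
        states[id(root)] = rng.choice(4, size=n_sites, p=pi)
    leaves: Dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is not None:
            node_biased = in_biased[id(node)] and biased_model is not None
            if node_biased and not in_biased[id(parent)]:
                # entry into the biased clade: re-draw from its equilibrium
                states[id(node)] = rng.choice(
                    4, size=n_sites, p=np.asarray(biased_model.freqs))
            else:
                edge_model = biased_model if node_biased else model
                bl = node.edge.length or 0.0
                parent_states = states[id(parent)]
                out = np.empty(n_sites, dtype=int)
                for ci, r in enumerate(cat_rates):
                    mask = cats == ci
                    if not mask.any():
                        continue
                    p = edge_model.transition_matrix(bl * r)
                    cum = p.cumsum(axis=1)
                    u = rng.random(mask.sum())
                    rows = cum[parent_states[mask]]
                    out[mask] = (u[:, None] > rows).sum(axis=1)
                states[id(node)] = out
        if node.is_leaf():
            leaves[node.taxon.label] = states[id(node)]
    return leaves


def simulate_alignment(truth: GeneFamilyTruth, model: SimulationModel,
                       seed: Optional[int] = None) -> MultipleAlignment:
    """Evolve an in-frame alignment along the truth's gene tree.

    With a third-position frequency override, codon positions 1+2 evolve
    under the base model and position 3 under the override frequencies,
    reproducing the compositional heterogeneity seen at silent sites.
    """
    seed = truth.seed if seed is None else seed
    # independent stream from the gene-tree stage
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    n = model.site_count
    root12 = root3 = root_all = None
    if model.root_sequence is not None:
        lut = np.full(128, -1, dtype=int)
        for i, b in enumerate("ACGT"):
            lut[ord(b)] = i
        seq = lut[np.frombuffer(model.root_sequence.upper().encode(), np.uint8)]
        root_all = seq
        if model.third_position_freqs is not None:
            root12 = np.empty(2 * (n // 3), dtype=int)
            root12[0::2] = seq[0::3]
            root12[1::2] = seq[1::3]
            root3 = seq[2::3]
    if model.third_position_freqs is None:
        leaves = _evolve(truth.gene_tree, model.model, n, rng,
                         root_states=root_all)
        mats = {k: v for k, v in leaves.items()}
    else:
        n12, n3 = 2 * (n // 3), n // 3
        biased = model.third_position_bias_taxa
        if biased is None:
            clupeo = set(_LINEAGE_SPECIES["Clupeocephala"])
            biased = tuple(l for l, sp in truth.leaf_map.items()
                           if sp in clupeo)
        override = model.model.with_(freqs=model.third_position_freqs)
        base = _evolve(truth.gene_tree, model.model, n12, rng,
                       root_states=root12)
        fast_tree = dendropy.Tree(truth.gene_tree)
        for edge in fast_tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * model.third_position_rate
        third = _evolve(fast_tree, model.model, n3, rng,
                        biased_model=override, biased_taxa=biased,
                        root_states=root3)
        mats = {}
        for k in base:
            seq = np.empty(n, dtype=int)
            seq[0::3] = base[k][0::2]
            seq[1::3] = base[k][1::2]
            seq[2::3] = third[k]
            mats[k] = seq
    alphabet = np.array(list("ACGT"))
    records = [(name, "".join(alphabet[mats[name]]))
               for name in sorted(mats)]
    return MultipleAlignment(records, frame_offset=0)


def simulate_gene_family(scenario_id: str = "B6", seed: int = 0,
                         species_tree: Optional[dendropy.Tree] = None,
                         sim_model: Optional[SimulationModel] = None,
                         loss_spec: Optional[Sequence[Tuple[str, str]]] = None,
                         rate_multiplier: float = 1.0,
                         full_retention: bool = False):
    """Gene tree + alignment + truth record in one call."""
    truth = simulate_gene_tree(species_tree, scenario_id, loss_spec,
                               seed=seed, rate_multiplier=rate_multiplier,
                               full_retention=full_retention)
    model = sim_model if sim_model is not None else SimulationModel()
    aln = simulate_alignment(truth, model)
    return truth, aln
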