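import io

import numpy as np
import pytest

from rhodups.alignment import composition_homogeneity_test
from rhodups.reconcile import lca_reconcile
from rhodups.simulate import (GeneFamilyTruth, SimulationModel,
                              compact_species_tree, default_species_tree,
                              simulate_alignment, simulate_gene_family,
                              simulate_gene_tree)
from rhodups.substmodel import GTRGamma
from rhodups.trees import read_tree


@pytest.mark.parametrize("scenario,family_D", [("A1", 3), ("A2", 3),
                                               ("B1", 2), ("B6", 2),
                                               ("C1", 1), ("C4", 1)])
def test_truth_duplication_count_matches_scenario_family(scenario, family_D):
    truth = simulate_gene_tree(default_species_tree(), scenario, seed=1)
    assert truth.duplication_count == family_D
    assert sum(1 for k, _ in truth.events if k == "duplication") == family_D
    assert sum(1 for k, _ in truth.events if k == "loss") == truth.loss_count


def test_no_loss_scenario_c1_by_construction():
    truth = simulate_gene_tree(default_species_tree(), "C1",
                               full_retention=True)
    assert truth.duplication_count == 1
    assert truth.loss_count == 0


def test_b6_with_older_paralog_losses():
    truth = simulate_gene_tree(
        default_species_tree(), "B6", full_retention=True,
        loss_spec=[("Hiodon_2", "OtherOsteoglossomorpha")])
    assert truth.duplication_count == 2
    assert truth.loss_count == 2


def test_every_leaf_maps_to_an_extant_species():
    st = default_species_tree()
    species = {l.taxon.label for l in st.leaf_node_iter()}
    truth = simulate_gene_tree(st, "B6", seed=0)
    assert set(truth.leaf_map.values()) <= species
    assert set(truth.leaf_map) == {l.taxon.label
                                   for l in truth.gene_tree.leaf_node_iter()}


def test_reconciliation_recovers_truth_counts():
    st = default_species_tree()
    truth = simulate_gene_tree(st, "B6", seed=0)
    rec = lca_reconcile(truth.gene_tree, st, truth.leaf_map,
                        restrict_to_sampled=False)
    assert rec.duplication_count == truth.duplication_count
    assert rec.loss_count == truth.loss_count


def test_emptying_the_family_is_rejected():
    with pytest.raises(ValueError, match="every gene copy"):
        simulate_gene_tree(default_species_tree(), "C1",
                           loss_spec=[(t, "Gnathostomata") for t in
                                      ("Elops_dso", "Elops_fwo", "Hiodon_1",
                                       "Hiodon_2", "Osteo", "Clupeo_A",
                                       "Clupeo_B")])


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="unknown scenario"):
        simulate_gene_tree(default_species_tree(), "Q7")


def test_same_seed_reproduces_fasta_byte_for_byte(tmp_path):
    out = []
    for rep in range(2):
        truth, aln = simulate_gene_family("B6", seed=9,
                                          species_tree=compact_species_tree(),
                                          sim_model=SimulationModel(site_count=300))
        path = tmp_path / f"r{rep}.fasta"
        aln.to_fasta(path)
        out.append(path.read_bytes())
    assert out[0] == out[1]


def test_zero_branch_lengths_give_identical_sequences():
    tree = read_tree("((a:0.0,b:0.0):0.0,(c:0.0,d:0.0):0.0);")
    truth = GeneFamilyTruth("C1", tree, [], {x: "Elops" for x in "abcd"},
                            {x: "Elops_dso" for x in "abcd"}, seed=3)
    aln = simulate_alignment(truth, SimulationModel(site_count=120), seed=3)
    seqs = {s for _, s in aln.records()}
    assert len(seqs) == 1


def test_long_branch_reaches_stationarity():
    """After 50 expected substitutions the tip composition equals the
    stationary frequencies to within binomial error."""
    tree = read_tree("(a:0.0,b:50.0);")
    truth = GeneFamilyTruth("C1", tree, [], {"a": "Elops", "b": "Danio"},
                            {"a": "Elops_dso", "b": "Elops_dso"}, seed=5)
    model = GTRGamma(rates=(1.5, 4.0, 1.0, 1.2, 6.0, 1.0),
                     freqs=(0.22, 0.28, 0.24, 0.26), alpha=0.5, ncat=4)
    n = 10000
    aln = simulate_alignment(truth, SimulationModel(model=model, site_count=n),
                             seed=5)
    seq = aln.sequence("b")
    for base, freq in zip("ACGT", model.freqs):
        obs = seq.count(base) / n
        sigma = np.sqrt(freq * (1 - freq) / n)
        assert abs(obs - freq) < 3.5 * sigma


def test_third_position_bias_detected_only_at_position_three():
    hits = {1: 0, 2: 0, 3: 0}
    n_rep = 20
    for seed in range(n_rep):
        _, aln = simulate_gene_family(
            "B6", seed=seed, species_tree=compact_species_tree(),
            sim_model=SimulationModel(site_count=996,
                                      third_position_freqs=(0.1, 0.4, 0.1, 0.4)))
        for pos in (1, 2, 3):
            hits[pos] += composition_homogeneity_test(aln, pos).p_value < 0.05
    assert hits[3] >= 0.9 * n_rep
    assert hits[1] <= 0.1 * n_rep + 1
    assert hits[2] <= 0.1 * n_rep + 1


def test_truth_record_serialises(tmp_path):
    truth = simulate_gene_tree(compact_species_tree(), "B5", seed=2)
    text = truth.to_json()
    assert '"scenario_id": "B5"' in text
    assert '"duplication_count": 2' in text


def test_ml_tree_reconciliation_recovers_duplication_count(b6_family, gtr_model):
    """Round trip: search the simulated alignment, root the ML tree with
    the outgroup, reconcile — the true duplication count (2) comes back."""
    from rhodups.search import ml_search
    truth, aln = b6_family
    res = ml_search(aln, gtr_model, n_starts=1, seed=6)
    tree = res.tree
    og = tree.find_node_with_taxon_label(truth.outgroup_taxa()[0])
    bl = og.edge.length or 0.1
    tree.reroot_at_edge(og.edge, length1=bl / 2, length2=bl / 2)
    tree.suppress_unifurcations()
    rec = lca_reconcile(tree, compact_species_tree(), truth.leaf_map)
    assert rec.duplication_count == truth.duplication_count
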