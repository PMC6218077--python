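import itertools
import math

import numpy as np
import pytest

from rhodups.alignment import MultipleAlignment, ry_recode
from rhodups.likelihood import (TreeLikelihood, optimize_parameters,
                                site_log_likelihoods)
from rhodups.substmodel import GTRGamma
from rhodups.trees import read_tree

from conftest import random_alignment

_BASES = "ACGT"
_I = {b: i for i, b in enumerate(_BASES)}


def brute_force_site_logliks(lengths, aln, model):
    """Exhaustive ancestral-state enumeration for ((A,B),(C,D))."""
    tA, tB, tu, tC, tD, tv = lengths
    pi = np.asarray(model.freqs)
    cr = model.category_rates
    out = []
    for s in range(aln.length):
        lik = 0.0
        for r in cr:
            P = lambda t: model.transition_matrix(t * r)
            PA, PB, PC, PD, Pu, Pv = (P(tA), P(tB), P(tC), P(tD), P(tu), P(tv))
            obs = [aln.matrix[i, s] for i in range(4)]
            for root, x, y in itertools.product(range(4), repeat=3):
                lik += (pi[root] * Pu[root, x] * Pv[root, y]
                        * PA[x, _I[obs[0]]] * PB[x, _I[obs[1]]]
                        * PC[y, _I[obs[2]]] * PD[y, _I[obs[3]]])
        out.append(np.log(lik / len(cr)))
    return np.array(out)


def test_pruning_matches_enumeration_oracle(gtr_model):
    rng = np.random.default_rng(7)
    lengths = [0.1, 0.25, 0.07, 0.4, 0.02, 0.13]
    tree = read_tree("((A:0.1,B:0.25):0.07,(C:0.4,D:0.02):0.13);")
    aln = random_alignment(rng, list("ABCD"), 30)
    site, total = site_log_likelihoods(tree, aln, gtr_model)
    expect = brute_force_site_logliks(lengths, aln, gtr_model)
    assert np.max(np.abs(site - expect)) < 1e-10
    assert total == pytest.approx(expect.sum())


def test_all_missing_column_has_zero_logdensity(gtr_model):
    tree = read_tree("((A:0.1,B:0.2):0.1,(C:0.1,D:0.1):0.05);")
    aln = MultipleAlignment([("A", "NA"), ("B", "NC"), ("C", "-G"), ("D", "NT")])
    site, _ = site_log_likelihoods(tree, aln, gtr_model)
    assert site[0] == pytest.approx(0.0, abs=1e-12)


def test_loglik_invariant_to_rerooting(gtr_model):
    """Pulley principle: a reversible model cannot see the root position."""
    rng = np.random.default_rng(17)
    tree = read_tree("(((A:0.11,B:0.31):0.07,(C:0.2,D:0.05):0.12):0.04,"
                     "(E:0.3,F:0.08):0.09);")
    aln = random_alignment(rng, list("ABCDEF"), 40)
    _, base = site_log_likelihoods(tree, aln, gtr_model)
    for i in range(20):
        t2 = read_tree("(((A:0.11,B:0.31):0.07,(C:0.2,D:0.05):0.12):0.04,"
                       "(E:0.3,F:0.08):0.09);")
        edges = [e for e in t2.preorder_edge_iter()
                 if e.head_node.parent_node is not None and e.length]
        edge = edges[i % len(edges)]
        frac = rng.uniform(0.2, 0.8)
        t2.reroot_at_edge(edge, length1=edge.length * frac,
                          length2=edge.length * (1 - frac))
        _, lnl = site_log_likelihoods(t2, aln, gtr_model)
        assert abs(lnl - base) < 1e-8


def test_jc_two_taxon_distance_closed_form():
    p = 0.22
    n = 5000
    k = int(n * p)
    seq_a = "A" * n
    seq_b = "G" * (k - 2 * (k // 3)) + "C" * (k // 3) + "T" * (k // 3) + \
            "A" * (n - k)
    aln = MultipleAlignment([("a", seq_a), ("b", seq_b)])
    tree = read_tree("(a:0.05,b:0.05);")
    jc = GTRGamma(ncat=1)
    fitted, _, _ = optimize_parameters(tree, aln, jc, what="branch_lengths")
    dist = sum(e.length for e in fitted.preorder_edge_iter() if e.length)
    p_obs = sum(a != b for a, b in zip(seq_a, seq_b)) / n
    expected = -0.75 * math.log(1 - 4 * p_obs / 3)
    assert dist == pytest.approx(expected, abs=1e-4)


def test_two_identical_sequences_fit_zero_distance():
    aln = MultipleAlignment([("a", "ACGTACGTAC" * 10), ("b", "ACGTACGTAC" * 10)])
    tree = read_tree("(a:0.3,b:0.2);")
    fitted, _, lnl = optimize_parameters(tree, aln, GTRGamma(ncat=1),
                                         what="branch_lengths")
    dist = sum(e.length for e in fitted.preorder_edge_iter() if e.length)
    assert dist < 1e-6


def test_ambiguity_superset_dominance(gtr_model):
    """Replacing a base by a compatible ambiguity never lowers a site's
    likelihood (marginalisation adds non-negative terms)."""
    rng = np.random.default_rng(3)
    tree = read_tree("((A:0.1,B:0.3):0.05,(C:0.2,D:0.15):0.08);")
    aln = random_alignment(rng, list("ABCD"), 25)
    site0, _ = site_log_likelihoods(tree, aln, gtr_model)
    recs = {i: list(s) for i, s in aln.records()}
    widen = {"A": "R", "G": "R", "C": "Y", "T": "Y"}
    row = list(recs["B"])
    recs["B"] = [widen[c] for c in row]
    aln2 = MultipleAlignment([(i, "".join(recs[i])) for i in aln.ids])
    site1, _ = site_log_likelihoods(tree, aln2, gtr_model)
    assert np.all(site1 >= site0 - 1e-12)


def test_pattern_compression_consistency(gtr_model):
    rng = np.random.default_rng(5)
    tree = read_tree("((A:0.1,B:0.3):0.05,(C:0.2,D:0.15):0.08);")
    base = random_alignment(rng, list("ABCD"), 12)
    doubled = MultipleAlignment([(i, s + s) for i, s in base.records()])
    _, l1 = site_log_likelihoods(tree, base, gtr_model)
    _, l2 = site_log_likelihoods(tree, doubled, gtr_model)
    assert l2 == pytest.approx(2 * l1, abs=1e-9)


def test_edge_closure_matches_full_likelihood(gtr_model):
    rng = np.random.default_rng(9)
    tree = read_tree("((A:0.1,B:0.3):0.05,(C:0.2,D:0.15):0.08);")
    aln = random_alignment(rng, list("ABCD"), 60)
    eng = TreeLikelihood(tree, aln, gtr_model)
    for e in eng._idx.free_edges:
        f = eng._edge_lnl_closure(gtr_model, e)
        for t in (1e-6, 0.05, 0.7, 3.0):
            lengths = eng._idx.lengths.copy()
            lengths[e] = t
            assert f(t) == pytest.approx(eng.loglik(gtr_model, lengths),
                                         abs=1e-8)


def test_fit_is_monotone_and_reports_reproducible_loglik(b6_family, gtr_model):
    truth, aln = b6_family
    eng = TreeLikelihood(truth.gene_tree, aln, gtr_model)
    before = eng.loglik()
    res = eng.fit(optimize="branch_lengths")
    assert res.loglik >= before - 1e-6
    rescored = TreeLikelihood(res.tree, aln, res.model).loglik()
    assert rescored == pytest.approx(res.loglik, abs=1e-6)
    assert "log-likelihood" in res.summary()


def test_gamma_shape_recovery():
    """Fitting alpha on data simulated at alpha=0.5 lands near the truth."""
    from rhodups.simulate import (SimulationModel, compact_species_tree,
                                  simulate_gene_family)
    truth, aln = simulate_gene_family(
        "C1", seed=23, species_tree=compact_species_tree(),
        sim_model=SimulationModel(site_count=3000))
    tree = truth.gene_tree
    model = GTRGamma(rates=(1.5, 4.0, 1.0, 1.2, 6.0, 1.0),
                     freqs=(0.22, 0.28, 0.24, 0.26), alpha=1.0, ncat=4)
    _, fitted, _ = optimize_parameters(tree, aln, model, what="both")
    assert 0.3 <= fitted.alpha <= 0.8
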