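import itertools

import dendropy
import numpy as np
import pytest

from rhodups.acr import (CharacterMatrix, backbone_tree, count_gains,
                         fitch_acr, opsin_character_matrix)
from rhodups.trees import read_tree, random_resolve


def brute_min_changes(tree, character, states):
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    best = None
    for combo in itertools.product(states, repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        for leaf in tree.leaf_node_iter():
            obs = character[leaf.taxon.label]
            assign[id(leaf)] = obs
        changes = 0
        ok = True
        for node in tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            a, b = assign[id(node.parent_node)], assign[id(node)]
            if b == "?":
                continue
            if a != b:
                changes += 1
        if best is None or changes < best:
            best = changes
    return best


def brute_min_changes_with_missing(tree, character, states):
    """Missing leaves range over all states; minimise over those too."""
    missing = [l for l in tree.leaf_node_iter()
               if character[l.taxon.label] == "?"]
    best = None
    for combo in itertools.product(states, repeat=len(missing)):
        char2 = dict(character)
        for leaf, s in zip(missing, combo):
            char2[leaf.taxon.label] = s
        val = brute_min_changes(tree, char2, states)
        if best is None or val < best:
            best = val
    return best


def test_uniform_character_needs_no_changes():
    tree = read_tree("((a,b),(c,d));")
    res = fitch_acr(tree, {x: "1" for x in "abcd"})
    assert res.min_changes == 0
    for ss in res.node_states.values():
        assert ss == frozenset({"1"})


def test_min_changes_matches_brute_force_on_random_trees():
    rng = np.random.default_rng(55)
    states = ("0", "1", "2")
    for rep in range(50):
        n = int(rng.integers(4, 7))
        ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=ns)
        for i in range(n):
            node = dendropy.Node()
            node.taxon = ns.new_taxon(label=f"t{i}")
            tree.seed_node.add_child(node)
        random_resolve(tree, rng)
        labels = [f"t{i}" for i in range(n)]
        char = {l: str(rng.choice(["0", "1", "2", "?"], p=[.3, .3, .2, .2]))
                for l in labels}
        if all(v == "?" for v in char.values()):
            continue
        res = fitch_acr(tree, char, states=states)
        brute = brute_min_changes_with_missing(tree, char, states)
        assert res.min_changes == brute, (char, tree.as_string(schema="newick"))


def test_min_changes_invariant_to_rerooting():
    rng = np.random.default_rng(7)
    tree_s = "((a,(b,c)),((d,e),f));"
    char = {"a": "0", "b": "1", "c": "?", "d": "1", "e": "2", "f": "0"}
    base = fitch_acr(read_tree(tree_s), char).min_changes
    for leaf in "abdf":
        t = read_tree(tree_s)
        node = t.find_node_with_taxon_label(leaf)
        t.reroot_at_edge(node.edge)
        assert fitch_acr(t, char).min_changes == base


def test_adding_missing_taxon_changes_nothing():
    tree = read_tree("((a,b),(c,d));")
    char = {"a": "0", "b": "1", "c": "1", "d": "0"}
    base = fitch_acr(tree, char).min_changes
    tree2 = read_tree("((a,(b,x)),(c,d));")
    res2 = fitch_acr(tree2, {**char, "x": "?"})
    assert res2.min_changes == base


def test_two_separated_derived_tips_need_two_gains():
    tree = read_tree("(((a,b),(c,d)),((e,f),(g,h)));")
    char = dict.fromkeys("abcdefgh", "1")
    char["a"] = "2"
    char["h"] = "2"
    res = fitch_acr(tree, char)
    assert count_gains(res, "1", "2", None) == 2
    assert res.min_changes == 2


def test_single_leaf_clade_has_no_gains():
    tree = read_tree("((a,b),(c,d));")
    res = fitch_acr(tree, {"a": "2", "b": "1", "c": "1", "d": "1"})
    assert count_gains(res, "1", "2", "b") == 0


def test_multifurcations_handled_natively():
    tree = read_tree("(a,b,c,(d,e));")
    res = fitch_acr(tree, {"a": "0", "b": "1", "c": "1", "d": "1", "e": "0"})
    assert res.min_changes == 2


def test_packaged_matrix_copy_number_gains_in_teleosts():
    """The copy-number coding implies three independent 1->2 gains of the
    intron-less rhodopsin inside the Teleostei (eel-like fishes, Hiodon,
    and the otocephalan clupeocephalans)."""
    tree = backbone_tree()
    cm = opsin_character_matrix()
    res = fitch_acr(tree, cm.column("intronless_rh1_copies"))
    assert count_gains(res, "1", "2", "Teleostei") == 3


def test_packaged_matrix_single_intron_loss():
    tree = backbone_tree()
    cm = opsin_character_matrix()
    res = fitch_acr(tree, cm.column("rh1_intron_presence"))
    assert res.min_changes == 1
    assert count_gains(res, "1", "0", None) == 1


def test_character_matrix_round_trip(tmp_path):
    cm = opsin_character_matrix()
    path = tmp_path / "chars.tsv"
    cm.to_tsv(path)
    back = CharacterMatrix.from_tsv(path)
    assert back.table.equals(cm.table)
    assert back.column("exo_rh1_presence")["Polypterus"] == "?"


def test_annotated_newick_mentions_states():
    tree = read_tree("((a,b),c);")
    res = fitch_acr(tree, {"a": "1", "b": "0", "c": "0"})
    text = res.annotated_newick()
    assert "states" in text
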