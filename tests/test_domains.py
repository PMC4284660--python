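from itertools import product

import dendropy
import numpy as np
import pandas as pd
import pytest

from chordevo.domains import (
    BranchGains,
    PairMatrix,
    dollo_gains,
    extract_pairs,
    gain_rate,
    pair_matrix,
    presence_absence_tree,
    promiscuity_rank,
    resolve_architecture,
)
from chordevo.io import DOMAIN_COLUMNS
from oracles import dollo_min_single_gain


def _tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestExtractPairs:
    def test_adjacent_excludes_tandem_self_pairs(self):
        pairs = extract_pairs({"p": ["Ig", "Ig", "TIR"]}, mode="adjacent")
        assert pairs == {frozenset({"Ig", "TIR"})}

    def test_cooccur_gives_all_unordered_pairs(self):
        pairs = extract_pairs({"p": ["A", "B", "C"]}, mode="cooccur")
        assert pairs == {frozenset(x) for x in [("A", "B"), ("A", "C"), ("B", "C")]}

    def test_adjacent_subset_of_cooccur(self):
        rng = np.random.default_rng(3)
        vocab = [f"D{i}" for i in range(8)]
        for _ in range(20):
            arch = {"p": [vocab[i] for i in rng.integers(0, 8, rng.integers(2, 6))]}
            assert extract_pairs(arch, "adjacent") <= extract_pairs(arch, "cooccur")

    def test_overlap_resolution_prefers_better_evalue(self):
        doms = pd.DataFrame(
            [
                ("p", "Good", 10, 50, 1e-30),
                ("p", "Bad", 30, 70, 1e-5),
                ("p", "Next", 60, 90, 1e-20),
            ],
            columns=DOMAIN_COLUMNS,
        )
        arch = resolve_architecture(doms)
        assert arch["p"] == ["Good", "Next"]

    def test_planted_novel_pairs_recovered_by_set_difference(self, ancestor):
        from chordevo import simulate as sim

        g = 6
        desc, log = sim.evolve_lineage(
            ancestor, sim.LineageParams(domain_pair_gain=g), seed=61
        )
        _, _, doms_anc, _ = ancestor.render()
        _, _, doms_desc, _ = desc.render()
        pairs_anc = extract_pairs(resolve_architecture(doms_anc))
        pairs_desc = extract_pairs(resolve_architecture(doms_desc))
        novel = pairs_desc - pairs_anc
        truth = {
            frozenset({e.data["domain_type"]}) for e in log if e.kind == "domain_gain"
        }
        # every gained type is new to the vocabulary, so each gain yields
        # exactly the novel pairs containing it
        gained_types = {e.data["domain_type"] for e in log if e.kind == "domain_gain"}
        assert len(gained_types) == g
        assert {t for p in novel for t in p if t in gained_types} == gained_types


class TestDollo:
    def test_pair_in_sister_leaves_gains_on_their_ancestor(self):
        matrix = PairMatrix(
            presence={
                "A": {frozenset({"x", "y"})},
                "B": {frozenset({"x", "y"})},
                "C": set(),
                "D": set(),
            }
        )
        res = dollo_gains(matrix, _tree("((A,B),(C,D));"))
        assert res.gains == {"A+B": 1}
        assert res.losses == {}

    def test_scattered_pair_gains_at_root_with_two_losses(self):
        matrix = PairMatrix(
            presence={
                "A": {frozenset({"x", "y"})},
                "B": set(),
                "C": {frozenset({"x", "y"})},
                "D": set(),
            }
        )
        res = dollo_gains(matrix, _tree("((A,B),(C,D));"))
        assert sum(res.gains.values()) == 1
        assert sum(res.losses.values()) == 2
        assert set(res.losses) == {"B", "D"}

    @pytest.mark.parametrize(
        "newick,leaves",
        [
            ("((A,B),(C,D));", "ABCD"),
            ("(((A,B),C),(D,E));", "ABCDE"),
            ("((A,(B,(C,D))),E);", "ABCDE"),
        ],
    )
    def test_matches_brute_force_on_all_presence_patterns(self, newick, leaves):
        tree = _tree(newick)
        children = {}

        def walk(node):
            label = (
                node.taxon.label
                if node.taxon
                else "+".join(sorted(l.taxon.label for l in node.leaf_iter()))
            )
            children[label] = []
            for c in node.child_nodes():
                children[label].append(walk(c))
            return label

        root = walk(tree.seed_node)
        for bits in product([0, 1], repeat=len(leaves)):
            present = {l for l, b in zip(leaves, bits) if b}
            if not present:
                continue
            matrix = PairMatrix(
                presence={
                    l: ({frozenset({"x", "y"})} if l in present else set())
                    for l in leaves
                }
            )
            res = dollo_gains(matrix, tree)
            _, oracle_losses, oracle_total = dollo_min_single_gain(children, root, present)
            assert sum(res.gains.values()) == 1
            assert sum(res.gains.values()) + sum(res.losses.values()) == oracle_total

    def test_total_gains_equal_observed_pairs(self, ancestor):
        rng = np.random.default_rng(9)
        species = list("ABCDE")
        vocab = [f"D{i}" for i in range(10)]
        presence = {
            sp: {
                frozenset(rng.choice(vocab, size=2, replace=False))
                for _ in range(rng.integers(3, 10))
            }
            for sp in species
        }
        matrix = PairMatrix(presence=presence)
        res = dollo_gains(matrix, _tree("(((A,B),C),(D,E));"))
        assert res.total_gains == len(matrix.all_pairs)

    def test_vocabulary_split_partitions_pairs(self):
        matrix = PairMatrix(
            presence={"A": {frozenset({"V1", "x"}), frozenset({"x", "y"})}, "B": set()}
        )
        specific, ancient = matrix.vocabulary_split({"V1"})
        assert len(specific) + len(ancient) == len(matrix.all_pairs)
        assert specific == {frozenset({"V1", "x"})}


class TestRatesAndPromiscuity:
    def test_gain_rate_arithmetic(self):
        gains = BranchGains(gains={"b": 1300}, losses={})
        assert gain_rate(gains, {"b": 120.0})["b"] == pytest.approx(10.83, abs=0.01)
        assert gain_rate(BranchGains(gains={"b": 0}, losses={}), {"b": 50.0})["b"] == 0
        r1 = gain_rate(gains, {"b": 60.0})["b"]
        r2 = gain_rate(gains, {"b": 120.0})["b"]
        assert r1 == pytest.approx(2 * r2)

    def test_missing_duration_skipped_with_warning(self):
        gains = BranchGains(gains={"b": 5, "c": 2}, losses={})
        with pytest.warns(UserWarning, match="no duration"):
            rates = gain_rate(gains, {"b": 10.0})
        assert "c" not in rates

    def test_hub_domain_ranked_first(self):
        pairs = {frozenset({"hub", f"p{i}"}) for i in range(9)}
        pairs |= {frozenset({"a", "b"})}
        df = promiscuity_rank(pairs)
        assert df.iloc[0].domain_type == "hub"
        assert df.iloc[0].n_partners == 9


class TestPresenceAbsenceTree:
    def test_jaccard_distance_extremes(self):
        shared = {frozenset({"a", "b"})}
        matrix = PairMatrix(
            presence={
                "s1": shared,
                "s2": set(shared),
                "s3": {frozenset({"c", "d"})},
                "s4": {frozenset({"e", "f"})},
            }
        )
        tree = presence_absence_tree(matrix)
        tips = {t.name for t in tree.tips()}
        assert tips == {"s1", "s2", "s3", "s4"}
        # identical species separated by zero patristic distance
        assert tree.find("s1").distance(tree.find("s2")) == pytest.approx(0.0, abs=1e-9)

    def test_topology_recovered_from_simulated_gain_loss(self):
        rng = np.random.default_rng(13)
        newick = "(((A,B),(C,D)),(E,F));"
        ref = dendropy.Tree.get(data=newick, schema="newick")
        successes = 0
        n_rep = 10
        for rep in range(n_rep):
            presence = _simulate_matrix_on_tree(ref, rng, n_pairs=150, loss_rate=0.05)
            nj_tree = presence_absence_tree(PairMatrix(presence=presence))
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
            t2 = dendropy.Tree.get(data=str(nj_tree), schema="newick", taxon_namespace=tns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(
                t1, t2, is_bipartitions_updated=True
            )
            successes += rf == 0
        assert successes >= 9


def _simulate_matrix_on_tree(tree, rng, n_pairs, loss_rate):
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    presence = {l: set() for l in leaves}
    nodes = list(tree.preorder_node_iter())
    for i in range(n_pairs):
        pair = frozenset({f"d{i}a", f"d{i}b"})
        origin = nodes[rng.integers(0, len(nodes))]
        state = {}

        def push(node, has):
            if has and rng.random() < loss_rate and node is not origin:
                has = False
            if not node.child_nodes() and has:
                presence[node.taxon.label].add(pair)
            for c in node.child_nodes():
                push(c, has)

        push(origin, True)
    return presence
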