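"""Expansion-level classification and Brownian-motion ancestral states."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from serpinas import expansion_phylo as ep
from serpinas import synthetic_data as sd


def labeled_tree(newick, rows):
    meta = pd.DataFrame(rows).set_index("leaf")
    return ep.TaxonLabeledTree.from_newick(newick, meta)


def exhaustive_level(ttree, a, b, ladder):
    """Oracle: scan all leaves under MRCA(a, b) for the lowest shared rank."""
    mrca = ttree.tree.mrca(taxon_labels=[a, b])
    leaves = [lf.taxon.label for lf in mrca.leaf_iter()]
    for rank, key in enumerate(ladder):
        if len({ttree.metadata.loc[x, key] for x in leaves}) == 1:
            return rank
    return len(ladder)


SIX_LEAF = labeled_tree(
    "(((a1:1,a2:1):1,(b1:1,c1:1):1):1,(d1:1,e1:1):1);",
    [
        dict(leaf="a1", gene="gA", species="s1", genus="g1", family="f1", order="o1"),
        dict(leaf="a2", gene="gA2", species="s1", genus="g1", family="f1", order="o1"),
        dict(leaf="b1", gene="gB", species="s2", genus="g1", family="f1", order="o1"),
        dict(leaf="c1", gene="gC", species="s3", genus="g2", family="f1", order="o1"),
        dict(leaf="d1", gene="gD", species="s1", genus="g1", family="f1", order="o1"),
        dict(leaf="e1", gene="gE", species="s4", genus="g3", family="f2", order="o2"),
    ],
)


class TestClassifyPair:
    def test_same_species_cherry_is_rank_zero(self):
        rec = ep.classify_pair_expansion(SIX_LEAF, "a1", "a2", "gene")
        assert (rec.level, rec.rank) == ("species-specific", 0)

    def test_family_level_clade(self):
        """MRCA(a1, c1) spans two genera of one family -> family-specific."""
        rec = ep.classify_pair_expansion(SIX_LEAF, "a1", "c1", "gene")
        assert rec.rank == exhaustive_level(SIX_LEAF, "a1", "c1",
                                            ep.GENE_SCALE_LADDER) == 2
        assert rec.level == "family-specific"

    def test_exon_scale_genus_level(self):
        tree = labeled_tree(
            "((x1:1,(x2:1,y1:1):1):1,z1:1);",
            [dict(leaf="x1", gene="gX", species="s1", genus="g1", family="f1", order="o1"),
             dict(leaf="x2", gene="gX", species="s1", genus="g1", family="f1", order="o1"),
             dict(leaf="y1", gene="gY", species="s2", genus="g1", family="f1", order="o1"),
             dict(leaf="z1", gene="gZ", species="s9", genus="g9", family="f9", order="o9")])
        rec = ep.classify_pair_expansion(tree, "x1", "x2", "exon")
        assert (rec.level, rec.rank) == ("genus-specific", 1)

    def test_identical_leaves_rejected(self):
        with pytest.raises(ValueError):
            ep.classify_pair_expansion(SIX_LEAF, "a1", "a1")

    def test_symmetric_and_matches_oracle_on_all_pairs(self):
        for a, b in itertools.combinations(sorted(SIX_LEAF.leaf_labels()), 2):
            r1 = ep.classify_pair_expansion(SIX_LEAF, a, b, "gene")
            r2 = ep.classify_pair_expansion(SIX_LEAF, b, a, "gene")
            assert r1.rank == r2.rank == exhaustive_level(
                SIX_LEAF, a, b, ep.GENE_SCALE_LADDER)

    def test_rank_monotone_under_foreign_grafts(self):
        """Adding taxonomically more distant leaves inside the MRCA clade
        never lowers the pair's rank."""
        base_rows = [
            dict(leaf="a1", gene="gA", species="s1", genus="g1", family="f1", order="o1"),
            dict(leaf="a2", gene="gA2", species="s1", genus="g1", family="f1", order="o1"),
        ]
        grafts = [
            dict(leaf="x", gene="gX", species="s1", genus="g1", family="f1", order="o1"),
            dict(leaf="x", gene="gX", species="s2", genus="g1", family="f1", order="o1"),
            dict(leaf="x", gene="gX", species="s3", genus="g2", family="f1", order="o1"),
            dict(leaf="x", gene="gX", species="s4", genus="g3", family="f2", order="o1"),
            dict(leaf="x", gene="gX", species="s5", genus="g4", family="f3", order="o2"),
        ]
        last = -1
        for graft in grafts:
            tree = labeled_tree("((a1:1,x:1):1,a2:1);", base_rows + [graft])
            rank = ep.classify_pair_expansion(tree, "a1", "a2", "gene").rank
            assert rank >= last
            last = rank


class TestRankTable:
    def test_tally_equals_brute_force_over_all_pairs(self):
        ttree, _ = sd.simulate_labeled_tree(seed=5)
        pairs = ep.classify_all_pairs(ttree, "gene")
        seen = {(r.leaf_a, r.leaf_b) for r in pairs.itertuples()}
        expected = set()
        by_species = {}
        for leaf in ttree.leaf_labels():
            by_species.setdefault(ttree.rank_of(leaf, "species"), []).append(leaf)
        for leaves in by_species.values():
            for a, b in itertools.combinations(sorted(leaves), 2):
                expected.add((a, b))
        assert seen == expected
        for r in pairs.itertuples():
            assert r.rank == exhaustive_level(ttree, r.leaf_a, r.leaf_b,
                                              ep.GENE_SCALE_LADDER)

    def test_identical_groups_null_comparison(self):
        rows, blocks = [], []
        n = 0
        for ls in ("parasitoid", "nonparasitoid"):
            for b in range(3):
                a_, b_ = f"L{n}", f"L{n + 1}"
                n += 2
                for leaf in (a_, b_):
                    rows.append(dict(leaf=leaf, gene=leaf, species=f"s{ls}{b}",
                                     genus=f"g{ls}{b}", family="f", order="o",
                                     lifestyle=ls))
                blocks.append(f"({a_}:1,{b_}:1)")
        newick = "(" + ",".join(f"{blk}:1" for blk in blocks) + ");"
        ttree = labeled_tree(newick, rows)
        out = ep.expansion_rank_table(ttree, "gene")
        assert out["distributions"]["parasitoid"] == out["distributions"]["nonparasitoid"]
        assert out["rank_test"].p_value == pytest.approx(1.0)

    def test_planted_ranks_recovered_exactly(self):
        ttree, truth = sd.simulate_labeled_tree(seed=7)
        pairs = ep.classify_all_pairs(ttree, "gene").set_index(["leaf_a", "leaf_b"])
        for r in truth.itertuples():
            assert pairs.loc[(r.leaf_a, r.leaf_b), "rank"] == r.rank


class TestAncestralStates:
    def test_equal_branch_root_is_mean(self):
        tree = dendropy.Tree.get(data="(A:2,B:2);", schema="newick")
        tree.is_rooted = True
        est = ep.ancestral_states_bm(tree, {"A": 4.0, "B": 10.0})
        assert est["root"] == pytest.approx(7.0)

    def test_weighted_root_closed_form(self):
        tree = dendropy.Tree.get(data="(A:1,B:3);", schema="newick")
        tree.is_rooted = True
        est = ep.ancestral_states_bm(tree, {"A": 0.0, "B": 8.0})
        assert est["root"] == pytest.approx((0 / 1 + 8 / 3) / (1 + 1 / 3))

    def test_matches_numeric_likelihood_maximization(self):
        newick = "((A:1.0,B:2.0)ab:0.5,(C:1.5,(D:0.7,E:0.9)de:0.4)cde:1.1)root;"
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        tree.is_rooted = True
        tips = {"A": 1.0, "B": 4.0, "C": 0.0, "D": 6.0, "E": 7.0}
        est = ep.ancestral_states_bm(tree, tips)
        internals = ["ab", "de", "cde", "root"]
        edges = []  # (child key, parent key, length)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            child = node.taxon.label if node.is_leaf() else node.label
            edges.append((child, node.parent_node.label, node.edge.length))

        def neg_ll(x):
            vals = dict(zip(internals, x), **tips)
            return sum((vals[c] - vals[p]) ** 2 / v for c, p, v in edges)

        res = minimize(neg_ll, np.zeros(4), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        for key, val in zip(internals, res.x):
            assert est[key] == pytest.approx(val, abs=1e-5)

    def test_affine_equivariance_and_leaf_order_invariance(self):
        t1 = dendropy.Tree.get(data="((A:1,B:2):1,C:3);", schema="newick")
        t2 = dendropy.Tree.get(data="(C:3,(B:2,A:1):1);", schema="newick")
        for t in (t1, t2):
            t.is_rooted = True
        tips = {"A": 2.0, "B": 5.0, "C": 11.0}
        e1 = ep.ancestral_states_bm(t1, tips)
        e2 = ep.ancestral_states_bm(t2, tips)
        assert e1["root"] == pytest.approx(e2["root"])
        scaled = ep.ancestral_states_bm(t1, {k: 3 * v + 1 for k, v in tips.items()})
        assert scaled["root"] == pytest.approx(3 * e1["root"] + 1)

    def test_zero_length_branch_warns(self):
        tree = dendropy.Tree.get(data="(A:0,B:1);", schema="newick")
        tree.is_rooted = True
        with pytest.warns(UserWarning):
            ep.ancestral_states_bm(tree, {"A": 1.0, "B": 2.0})

    def test_missing_tip_value_raises(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        tree.is_rooted = True
        with pytest.raises(ValueError, match="B"):
            ep.ancestral_states_bm(tree, {"A": 1.0})
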