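"""Rank tests, chi-square, contrasts, Grafen lengths, dependent-correlation
comparison — each against an independent oracle."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy import stats as sps

from serpinas import phylo_stats as ps


def tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestGrafen:
    def test_two_leaf_tree_unit_branches(self):
        g = ps.grafen_branch_lengths(tree("(A,B);"))
        lengths = [n.edge.length for n in g.leaf_node_iter()]
        assert lengths == [1.0, 1.0]

    def test_balanced_four_leaf_hand_values(self):
        g = ps.grafen_branch_lengths(tree("((A,B),(C,D));"), rho=1.0)
        internal = [n for n in g.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
        assert [n.edge.length for n in internal] == pytest.approx([2 / 3, 2 / 3])
        assert [n.edge.length for n in g.leaf_node_iter()] == pytest.approx(
            [1 / 3] * 4)

    def test_rho_zero_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            g = ps.grafen_branch_lengths(tree("((A,B),C);"), rho=0.0)
        # all internal heights collapse to 1: internal branch length 0
        internal = [n for n in g.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
        assert internal[0].edge.length == pytest.approx(0.0)


def gls_contrast_oracle(newick, labels, lengths_and_values):
    """Brute-force contrasts via the phylogenetic covariance matrix: the
    contrast coefficients from recursive pruning are validated against
    GLS whitening (each standardized contrast has unit variance and zero
    covariance with the others under BM)."""
    t = tree(newick)
    taxa = sorted(labels)
    # covariance = shared path length from root
    pdm = {}
    for leaf in t.leaf_node_iter():
        path, node = [], leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        pdm[leaf.taxon.label] = path
    V = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            shared = set(pdm[a]) & set(pdm[b])
            V[i, j] = sum(n.edge.length or 0.0 for n in shared
                          if n.parent_node is not None)
    return taxa, V


class TestContrasts:
    def test_two_tip_closed_form(self):
        cs = ps.independent_contrasts(tree("(A:1,B:1);"), {"A": 4.0, "B": 10.0})
        assert abs(cs.contrasts[0]) == pytest.approx(6 / math.sqrt(2))

    def test_contrasts_whiten_under_gls_oracle(self):
        """On a 4-tip tree, the vector of standardized contrasts c = L(x)
        must satisfy cov(c) = I under BM, i.e. the implied linear map L
        obeys L V L' = I.  We recover L column-by-column from unit inputs."""
        newick = "((A:1,B:2):0.5,(C:1.5,D:0.7):1.2);"
        taxa, V = gls_contrast_oracle(newick, "ABCD", None)
        basis = []
        for k in range(4):
            x = {lab: float(i == k) for i, lab in enumerate(taxa)}
            basis.append(ps.independent_contrasts(tree(newick), x).contrasts)
        L = np.column_stack(basis)  # contrasts are linear in tip values
        assert L @ V @ L.T == pytest.approx(np.eye(3), abs=1e-10)

    def test_leaf_order_invariance(self):
        vals = {"A": 1.0, "B": 5.0, "C": 2.0}
        c1 = ps.independent_contrasts(tree("((A:1,B:1):1,C:2);"), vals)
        c2 = ps.independent_contrasts(tree("(C:2,(B:1,A:1):1);"), vals)
        assert sorted(np.abs(c1.contrasts)) == pytest.approx(
            sorted(np.abs(c2.contrasts)))

    def test_bm_contrasts_approximately_standard_normal(self):
        """Traits simulated under BM yield contrasts passing Shapiro in at
        least 90% of trees."""
        rng = np.random.default_rng(77)
        passes = 0
        n_trees = 60
        for _ in range(n_trees):
            taxa = [f"t{i}" for i in range(16)]
            newick = taxa[0]
            for lab in taxa[1:]:
                newick = f"({newick}:{rng.uniform(0.5, 2):.3f},{lab}:{rng.uniform(0.5, 2):.3f})"
            t = tree(newick + ";")
            vals = {}

            def simulate(node, x):
                for child in node.child_nodes():
                    xc = x + rng.normal(0, math.sqrt(child.edge.length))
                    if child.is_leaf():
                        vals[child.taxon.label] = xc
                    else:
                        simulate(child, xc)

            simulate(t.seed_node, 0.0)
            cs = ps.independent_contrasts(t, vals)
            if sps.shapiro(cs.contrasts).pvalue > 0.05:
                passes += 1
        assert passes >= 0.9 * n_trees

    def test_missing_tip_raises(self):
        with pytest.raises(ValueError, match="B"):
            ps.independent_contrasts(tree("(A:1,B:1);"), {"A": 1.0})

    def test_polytomy_resolved_with_warning(self):
        with pytest.warns(UserWarning, match="polytom"):
            cs = ps.independent_contrasts(tree("(A:1,B:1,C:1);"),
                                          {"A": 1.0, "B": 2.0, "C": 3.0})
        assert len(cs) == 2


class TestCorrelationThroughOrigin:
    def test_perfect_correlations(self):
        x = np.array([1.0, -2.0, 3.0, 0.5])
        assert ps.correlation_through_origin(x, x).statistic == pytest.approx(1.0)
        assert ps.correlation_through_origin(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            r = ps.correlation_through_origin(x, y)
            assert r.statistic == pytest.approx(
                np.sum(x * y) / math.sqrt(np.sum(x * x) * np.sum(y * y)))
            t = r.statistic * math.sqrt(11 / (1 - r.statistic ** 2))
            assert r.p_value == pytest.approx(2 * sps.t.sf(abs(t), 11))

    def test_zero_variance_undefined(self):
        res = ps.correlation_through_origin(np.zeros(5), np.ones(5))
        assert not res.defined


class TestRankTests:
    def test_u_statistic_exhaustive_small_groups(self):
        res = ps.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 * 1/20

    def test_exact_branch_equals_enumeration_with_ties(self, rng):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0]
        res = ps.mann_whitney_u(x, y)
        pooled = np.array(x + y)
        ranks = sps.rankdata(pooled)
        u_obs = ranks[:4].sum() - 4 * 5 / 2
        us = [ranks[list(c)].sum() - 10.0
              for c in itertools.combinations(range(7), 4)]
        us = np.array(us)
        expected = min(1.0, 2 * min((us <= u_obs + 1e-9).mean(),
                                    (us >= u_obs - 1e-9).mean()))
        assert res.p_value == pytest.approx(expected)

    def test_exact_and_asymptotic_branches_agree_at_cutoff(self, rng):
        """Near the enumeration cutoff the two branches give similar p."""
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6) + 0.5
            exact = ps.mann_whitney_u(x, y)
            approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic")
            assert exact.p_value == pytest.approx(float(approx.pvalue),
                                                  rel=0.35, abs=0.05)

    def test_signed_rank_identical_samples(self):
        res = ps.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_signed_rank_exact_enumeration(self):
        x = np.array([2.0, 4.0, 6.0, 9.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = ps.wilcoxon_signed_rank(x, y)
        # all differences positive: V = 10, exact two-sided p = 2/16
        assert res.statistic == 10.0
        assert res.p_value == pytest.approx(2 / 16)

    def test_chi2_matches_hand_formula(self):
        table = np.array([[10, 20], [30, 15]])
        res = ps.chi_square(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert res.statistic == pytest.approx(
            ((table - expected) ** 2 / expected).sum())

    def test_spearman_exact_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 5.0, 4.0]
        res = ps.spearman(x, y)
        rho = 1 - 6 * 2 / (5 * 24)
        assert res.statistic == pytest.approx(rho)
        # permutation p: fraction of |rho| >= observed over all 120 orders
        perms = itertools.permutations([1, 2, 3, 4, 5])
        rx = np.array([1, 2, 3, 4, 5], dtype=float)
        count = 0
        for p in perms:
            r = np.corrcoef(rx, np.array(p, dtype=float))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / 120)

    def test_degenerate_inputs_reported(self):
        assert not ps.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]).defined
        assert not ps.mann_whitney_u([], [1.0]).defined

    def test_dispatch(self):
        assert ps.rank_and_table_tests(([1.0, 2.0], [3.0, 4.0]), "mwu").name == "U"
        with pytest.raises(ValueError):
            ps.rank_and_table_tests(None, "anova")


def hittner_oracle(r_jk, r_jh, r_kh, n):
    """Independent transcription of the back-transformed-average z test for
    overlapping dependent correlations (Dunn & Clark 1969 covariance with
    the pooled correlation of Silver, Hittner & May)."""
    zjk = 0.5 * math.log((1 + r_jk) / (1 - r_jk))
    zjh = 0.5 * math.log((1 + r_jh) / (1 - r_jh))
    zbar = (zjk + zjh) / 2
    rbar = (math.exp(2 * zbar) - 1) / (math.exp(2 * zbar) + 1)
    num = r_kh * (1 - 2 * rbar ** 2) - 0.5 * rbar ** 2 * (
        1 - 2 * rbar ** 2 - r_kh ** 2)
    c = num / (1 - rbar ** 2) ** 2
    z = (zjk - zjh) * math.sqrt((n - 3) / (2 - 2 * c))
    p = 2 * (1 - sps.norm.cdf(abs(z)))
    return z, p


class TestCompareCorrelations:
    def test_equal_correlations_give_zero_z(self):
        res = ps.compare_correlations(0.4, 0.4, 0.2, 50)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("r1,r2,r12,n", [
        (0.5, 0.2, 0.1, 315),
        (0.48, 0.05, 0.3, 731),
        (-0.3, 0.4, 0.0, 60),
    ])
    def test_matches_independent_oracle(self, r1, r2, r12, n):
        res = ps.compare_correlations(r1, r2, r12, n)
        z, p = hittner_oracle(r1, r2, r12, n)
        assert res.statistic == pytest.approx(z)
        assert res.p_value == pytest.approx(p)

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            ps.compare_correlations(1.0, 0.2, 0.1, 50)

    def test_null_calibration_quick(self):
        """Type-I error near nominal over a reduced null sweep (the full
        2000-replicate calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(5)
        n, reps, hits = 100, 300, 0
        cov = np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.2], [0.3, 0.2, 1.0]])
        chol = np.linalg.cholesky(cov)
        for _ in range(reps):
            xyz = rng.normal(size=(n, 3)) @ chol.T
            r1 = ps.spearman(xyz[:, 0], xyz[:, 1]).statistic
            r2 = ps.spearman(xyz[:, 0], xyz[:, 2]).statistic
            r12 = ps.spearman(xyz[:, 1], xyz[:, 2]).statistic
            if ps.compare_correlations(r1, r2, r12, n).p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.09
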