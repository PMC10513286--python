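"""Statistical layer: rank tests, chi-square, Spearman correlation,
phylogenetic independent contrasts with Grafen branch lengths, correlation
through the origin, and comparison of dependent overlapping correlations.

Rank and table tests are computed with :mod:`scipy.stats` where the sample is
large enough for the tie-corrected normal approximation; below a size cutoff
(combined n <= 12 for rank-sum, n <= 12 pairs for signed-rank, n <= 10 for
Spearman) exact enumeration is used so that small fixtures get exact
p-values even in the presence of ties.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats as sps

EXACT_RANKSUM_CUTOFF = 12  # combined sample size
EXACT_SIGNEDRANK_CUTOFF = 12  # non-zero pairs
EXACT_SPEARMAN_CUTOFF = 10


@dataclass
class StatResult:
    """A named test statistic with its p-value."""

    name: str  # one of {"U", "W", "V", "chi2", "rho", "r_origin", "z"}
    statistic: float
    p_value: float
    n: int
    tails: int = 2
    defined: bool = True
    note: str = ""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if not self.defined:
            return f"StatResult({self.name} undefined: {self.note})"
        return (
            f"StatResult({self.name}={self.statistic:.6g}, "
            f"p={self.p_value:.4g}, n={self.n})"
        )


@dataclass
class ContrastSet:
    """Standardized independent contrasts, one per internal node."""

    node_ids: list
    contrasts: np.ndarray
    variances: np.ndarray
    node_values: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.contrasts)


# ---------------------------------------------------------------------------
# Branch lengths and contrasts
# ---------------------------------------------------------------------------

def grafen_branch_lengths(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Assign branch lengths from clade sizes (Grafen 1989).

    Each node receives height ``(n_descendant_leaves - 1) ** rho`` normalized
    so the root has height 1 and tips height 0; a branch length is the height
    difference between parent and child.  Operates on a clone.
    """
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    tree = tree.clone(depth=1)
    n_total = len(tree.leaf_nodes())
    if n_total < 2:
        raise ValueError("need >= 2 leaves for Grafen branch lengths")
    if rho <= 0:
        warnings.warn("rho <= 0 degenerates Grafen heights; proceeding anyway")
    denom = float(n_total - 1) ** rho
    heights = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            k = sum(1 for _ in node.leaf_iter())
            heights[node] = float(k - 1) ** rho / denom
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[node.parent_node] - heights[node]
            if node.edge.length < 0:
                raise ValueError("negative Grafen branch length (non-nested heights?)")
    return tree


def _resolve_polytomies(tree: dendropy.Tree, eps: float = 1e-12) -> dendropy.Tree:
    poly = [n for n in tree.preorder_node_iter() if len(n.child_nodes()) > 2]
    if poly:
        warnings.warn(
            f"resolving {len(poly)} polytomies arbitrarily with {eps}-length branches"
        )
        tree.resolve_polytomies()
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = eps
    return tree


def independent_contrasts(tree: dendropy.Tree, trait: dict) -> ContrastSet:
    """Felsenstein's (1985) phylogenetically independent contrasts.

    ``trait`` maps leaf taxon labels to values.  Contrasts are standardized
    differences ``(x_i - x_j) / sqrt(v_i + v_j)`` computed bottom-up, with
    ancestral values as branch-length weighted averages and the parent branch
    augmented by ``v_i v_j / (v_i + v_j)``.
    """
    tree = tree.clone(depth=1)
    tree = _resolve_polytomies(tree)
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label not in trait:
            raise ValueError(f"missing tip value for leaf {label!r}")
    node_ids, contrasts, variances = [], [], []
    values = {}
    lengths = {}
    node_values = {}
    for node in tree.postorder_node_iter():
        bl = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            values[node] = float(trait[node.taxon.label])
            lengths[node] = float(bl)
            continue
        children = node.child_nodes()
        if len(children) != 2:  # resolved above; root trifurcation handled too
            raise ValueError("contrasts require a bifurcating tree")
        c1, c2 = children
        v1, v2 = lengths[c1], lengths[c2]
        if v1 <= 0 and v2 <= 0:
            v1 = v2 = 1e-12
        x1, x2 = values[c1], values[c2]
        contrasts.append((x1 - x2) / math.sqrt(v1 + v2))
        variances.append(v1 + v2)
        label = node.label or f"node{len(contrasts)}"
        node_ids.append(label)
        values[node] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        node_values[label] = values[node]
        lengths[node] = float(bl) + v1 * v2 / (v1 + v2)
    return ContrastSet(
        node_ids=node_ids,
        contrasts=np.asarray(contrasts, dtype=float),
        variances=np.asarray(variances, dtype=float),
        node_values=node_values,
    )


def correlation_through_origin(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Correlation constrained through the origin, for contrast pairs.

    r = sum(xy) / sqrt(sum(x^2) sum(y^2)); p from a t distribution with
    n - 1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 contrasts")
    sxx = float(np.dot(x, x))
    syy = float(np.dot(y, y))
    if sxx == 0 or syy == 0:
        return StatResult("r_origin", math.nan, math.nan, n, defined=False,
                          note="zero variance")
    r = float(np.dot(x, y)) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    df = n - 1
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult("r_origin", r, min(p, 1.0) if not math.isnan(p) else p, n)


# ---------------------------------------------------------------------------
# Rank and table tests
# ---------------------------------------------------------------------------

def _rankdata(a):
    return sps.rankdata(a)


def mann_whitney_u(x, y) -> StatResult:
    """Two-sided Mann-Whitney U.  Statistic is U of the first sample
    (identical to R's wilcox.test W).  Exact enumeration for combined
    n <= EXACT_RANKSUM_CUTOFF (handles ties); tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return StatResult("U", math.nan, math.nan, len(x) + len(y),
                          defined=False, note="empty group")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    u1 = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    if np.all(pooled == pooled[0]):
        return StatResult("U", u1, 1.0, n1 + n2, note="all ties")
    if n1 + n2 <= EXACT_RANKSUM_CUTOFF:
        # enumerate all assignments of group-1 slots over the pooled ranks
        us = []
        idx = range(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            u = float(np.sum(ranks[list(combo)]) - n1 * (n1 + 1) / 2.0)
            us.append(u)
        us = np.asarray(us)
        tol = 1e-9
        p = 2.0 * min(np.mean(us <= u1 + tol), np.mean(us >= u1 - tol))
        p = min(1.0, p)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return StatResult("U", u1, p, n1 + n2)


def wilcoxon_signed_rank(x, y=None) -> StatResult:
    """Two-sided Wilcoxon signed-rank test (statistic V = sum of positive
    ranks).  Zero differences are dropped; exact sign enumeration for
    <= EXACT_SIGNEDRANK_CUTOFF non-zero pairs.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return StatResult("V", 0.0, 1.0, len(d), note="all differences zero")
    ranks = _rankdata(np.abs(nz))
    v = float(np.sum(ranks[nz > 0]))
    if n <= EXACT_SIGNEDRANK_CUTOFF:
        vs = []
        for signs in itertools.product((0.0, 1.0), repeat=n):
            vs.append(float(np.dot(ranks, signs)))
        vs = np.asarray(vs)
        tol = 1e-9
        p = 2.0 * min(np.mean(vs <= v + tol), np.mean(vs >= v - tol))
        p = min(1.0, p)
    else:
        res = sps.wilcoxon(nz, alternative="two-sided", correction=False,
                           mode="approx")
        p = float(res.pvalue)
    return StatResult("V", v, p, len(d))


def chi_square(table) -> StatResult:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a non-negative 2-D array")
    if table.sum() == 0 or np.any(table.sum(axis=0) == 0) or np.any(
            table.sum(axis=1) == 0):
        return StatResult("chi2", math.nan, math.nan, int(table.sum()),
                          defined=False, note="degenerate margin")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return StatResult("chi2", float(chi2), float(p), int(table.sum()))


def spearman(x, y) -> StatResult:
    """Two-sided Spearman rank correlation.  Exact permutation p for
    n <= EXACT_SPEARMAN_CUTOFF, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult("rho", math.nan, math.nan, n, defined=False,
                          note="constant input")
    rx, ry = _rankdata(x), _rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_CUTOFF:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(np.dot(rx_c, rx_c)) * float(np.dot(ry_c, ry_c)))
        rhos = (rx_c[perms] @ ry_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        res = sps.spearmanr(x, y)
        p = float(res.pvalue)
    return StatResult("rho", rho, min(p, 1.0), n)


def rank_and_table_tests(data, kind: str) -> StatResult:
    """Dispatch: kind in {"mwu", "wsrt", "chi2", "spearman"} with
    kind-appropriate ``data`` (pair of groups, pair of paired vectors,
    a table, or an (x, y) pair)."""
    if kind == "mwu":
        return mann_whitney_u(*data)
    if kind == "wsrt":
        return wilcoxon_signed_rank(*data) if len(data) == 2 else wilcoxon_signed_rank(data)
    if kind == "chi2":
        return chi_square(data)
    if kind == "spearman":
        return spearman(*data)
    raise ValueError(f"unknown test kind {kind!r}")


def compare_correlations(r1: float, r2: float, r_yz: float, n: int) -> StatResult:
    """Compare two dependent overlapping correlations sharing one variable
    (Hittner, May & Silver 2003).

    r1 = cor(x, y), r2 = cor(x, z), r_yz = cor(y, z).  Uses Dunn & Clark's z
    with the back-transformed average of the two correlations plugged into
    the covariance term; two-sided normal p.
    """
    for r in (r1, r2, r_yz):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 10:
        raise ValueError("n >= 10 required")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    rbar = math.tanh((z1 + z2) / 2.0)
    rb2 = rbar * rbar
    c = (r_yz * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r_yz * r_yz)) / (
        (1 - rb2) ** 2
    )
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = 2.0 * sps.norm.sf(abs(z))
    return StatResult("z", float(z), float(min(p, 1.0)), n)
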