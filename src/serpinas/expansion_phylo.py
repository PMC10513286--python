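"""Expansion-level classification on taxonomy-labeled trees and Brownian
motion ancestral state estimation.

A duplicated pair's expansion level is the lowest taxonomic rank shared by
ALL leaves under the pair's most recent common ancestor.  Rank ladders differ
by scale: gene-pair ladder species(0) < genus(1) < family(2) < order(3) <
not-specific(4); exon-pair ladder gene(0) < genus(1) < family(2) < order(3) <
not-specific(4).  Smaller ranks mean more recent expansions.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .phylo_stats import chi_square, mann_whitney_u

GENE_SCALE_LADDER = ("species", "genus", "family", "order")
EXON_SCALE_LADDER = ("gene", "genus", "family", "order")
NOT_SPECIFIC = "not specific"


@dataclass
class TaxonLabeledTree:
    """A rooted tree whose leaves carry gene/species/genus/family/order
    metadata and optional tip trait values."""

    tree: dendropy.Tree
    metadata: pd.DataFrame  # indexed by leaf label
    traits: dict = field(default_factory=dict)  # leaf label -> value

    def __post_init__(self):
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        self._leaf_labels = set(labels)

    @classmethod
    def from_newick(cls, newick: str, metadata: pd.DataFrame,
                    traits: dict | None = None) -> "TaxonLabeledTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        tree.is_rooted = True
        return cls(tree=tree, metadata=metadata, traits=traits or {})

    def leaf_labels(self) -> set:
        return set(self._leaf_labels)

    def rank_of(self, label: str, key: str) -> str:
        return str(self.metadata.loc[label, key])


@dataclass
class ExpansionRecord:
    pair: tuple
    scale: str  # "gene" or "exon"
    level: str
    rank: int


def _ladder(scale: str):
    if scale == "gene":
        return GENE_SCALE_LADDER
    if scale == "exon":
        return EXON_SCALE_LADDER
    raise ValueError(f"unknown scale {scale!r}")


def classify_pair_expansion(ttree: TaxonLabeledTree, a: str, b: str,
                            scale: str = "gene") -> ExpansionRecord:
    """Expansion level of leaves (a, b): lowest rank in the scale's ladder
    shared by every leaf under MRCA(a, b); 'not specific' (rank 4) when even
    the order is not shared."""
    if a == b:
        raise ValueError("pair must be two distinct leaves")
    ladder = _ladder(scale)
    mrca = ttree.tree.mrca(taxon_labels=[a, b])
    clade_leaves = [lf.taxon.label for lf in mrca.leaf_iter()]
    for leaf in clade_leaves:
        if leaf not in ttree.metadata.index:
            raise KeyError(f"leaf {leaf!r} lacks taxonomy metadata")
    for rank, key in enumerate(ladder):
        values = {ttree.rank_of(leaf, key) for leaf in clade_leaves}
        if len(values) == 1:
            return ExpansionRecord((a, b), scale, f"{key}-specific", rank)
    return ExpansionRecord((a, b), scale, NOT_SPECIFIC, len(ladder))


def same_unit_pairs(ttree: TaxonLabeledTree, scale: str = "gene"):
    """Every pair of leaves sharing the scale's base unit (same species for
    gene pairs, same gene for exon pairs)."""
    unit_key = "species" if scale == "gene" else "gene"
    groups: dict = {}
    for leaf in sorted(ttree.leaf_labels()):
        groups.setdefault(ttree.rank_of(leaf, unit_key), []).append(leaf)
    for unit in sorted(groups):
        for a, b in combinations(groups[unit], 2):
            yield a, b


def classify_all_pairs(ttree: TaxonLabeledTree, scale: str = "gene") -> pd.DataFrame:
    rows = []
    for a, b in same_unit_pairs(ttree, scale):
        rec = classify_pair_expansion(ttree, a, b, scale)
        unit_key = "species" if scale == "gene" else "gene"
        rows.append(dict(
            leaf_a=a, leaf_b=b, unit=ttree.rank_of(a, unit_key),
            scale=scale, level=rec.level, rank=rec.rank,
            lifestyle=str(ttree.metadata.loc[a].get("lifestyle", "unknown")),
        ))
    return pd.DataFrame(
        rows, columns=["leaf_a", "leaf_b", "unit", "scale", "level", "rank",
                       "lifestyle"])


def expansion_rank_table(ttree: TaxonLabeledTree, scale: str = "gene",
                         group_key: str = "lifestyle") -> dict:
    """Per-group distributions over ranks 0-4, a two-sided rank-sum
    comparison of the rank values, and per-rank 2x2 chi-square tests on
    proportions."""
    pairs = classify_all_pairs(ttree, scale)
    if pairs.empty:
        raise ValueError("no classifiable same-unit pairs")
    groups = {k: v for k, v in pairs.groupby(group_key) if k != "unknown"}
    names = sorted(groups)
    dist = {
        name: np.bincount(df["rank"].values, minlength=5).tolist()
        for name, df in groups.items()
    }
    out = {"pairs": pairs, "distributions": dist}
    if len(names) == 2:
        g1, g2 = names
        out["rank_test"] = mann_whitney_u(groups[g1]["rank"].values,
                                          groups[g2]["rank"].values)
        out["median_ranks"] = {g1: float(groups[g1]["rank"].median()),
                               g2: float(groups[g2]["rank"].median())}
        per_rank = {}
        for rank in range(5):
            a_hit = int((groups[g1]["rank"] == rank).sum())
            b_hit = int((groups[g2]["rank"] == rank).sum())
            table = [[a_hit, len(groups[g1]) - a_hit],
                     [b_hit, len(groups[g2]) - b_hit]]
            per_rank[rank] = chi_square(table)
        out["per_rank_chi2"] = per_rank
    return out


def ancestral_states_bm(ttree_or_tree, tip_values: dict) -> dict:
    """Maximum-likelihood ancestral states under Brownian motion.

    Estimates are the joint generalized-least-squares optimum: the internal
    values minimizing sum over edges of (x_child - x_parent)^2 / branch
    length (for a two-leaf tree the root is the branch-length-inverse
    weighted average of the tips).  Zero or missing terminal branch lengths
    are perturbed by 1e-8 with a warning.
    """
    tree = ttree_or_tree.tree if isinstance(ttree_or_tree, TaxonLabeledTree) else ttree_or_tree
    nodes = list(tree.preorder_node_iter())
    leaves = [n for n in nodes if n.is_leaf()]
    internals = [n for n in nodes if not n.is_leaf()]
    for leaf in leaves:
        if leaf.taxon.label not in tip_values:
            raise ValueError(f"missing tip value for {leaf.taxon.label!r}")
    idx = {node: i for i, node in enumerate(internals)}
    m = len(internals)
    A = np.zeros((m, m))
    b = np.zeros(m)
    warned = False
    for node in nodes:
        if node.parent_node is None:
            continue
        v = node.edge.length
        if v is None or v <= 0:
            if not warned:
                warnings.warn("zero-length branch perturbed by 1e-8")
                warned = True
            v = 1e-8
        w = 1.0 / v
        p = idx[node.parent_node]
        A[p, p] += w
        if node.is_leaf():
            b[p] += w * float(tip_values[node.taxon.label])
        else:
            c = idx[node]
            A[c, c] += w
            A[p, c] -= w
            A[c, p] -= w
    est = np.linalg.solve(A, b)
    out = {}
    for node, i in idx.items():
        label = node.label or ("root" if node.parent_node is None else f"n{i}")
        out[label] = float(est[i])
    return out


def write_annotated_newick(ttree: TaxonLabeledTree) -> str:
    buf = io.StringIO()
    ttree.tree.write(file=buf, schema="newick")
    return buf.getvalue()
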