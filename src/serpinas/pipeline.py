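"""End-to-end orchestration: simulate inputs, run every analysis stage, and
write a machine-readable results bundle with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import tempfile
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (as_census, codon_evolution, expansion_phylo, gene_models,
               motif_regulation, phylo_stats, splice_anatomy, synthetic_data)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1
# REL-family (NF-kB-like) binding motif used as the default planted/scanned
# PWM, standing in for the dorsal/Dif position-frequency matrices.
DEFAULT_MOTIF_CONSENSUS = "GGGAATTCCC"


def _stat_dict(res) -> dict:
    return {"name": res.name, "statistic": res.statistic,
            "p_value": res.p_value, "n": res.n, "defined": res.defined}


def taxonomy_newick(taxonomy_table: pd.DataFrame) -> str:
    """A cladogram from taxonomy nesting (order > family > genus > species),
    unit branch lengths; species names with spaces become underscored."""
    tree: dict = {}
    for row in taxonomy_table.itertuples():
        tree.setdefault(row.order, {}).setdefault(row.family, {}).setdefault(
            row.genus, set()).add(row.species.replace(" ", "_"))

    def render(node):
        if isinstance(node, set):
            items = sorted(node)
        else:
            items = [render(node[k]) for k in sorted(node)]
        if len(items) == 1:
            return items[0]
        return "(" + ",".join(f"{x}:1" for x in items) + ")"

    return render(tree) + ";"


def run_full_analysis(config=None, seed: int = 0, outdir=None) -> dict:
    """Run the synthetic end-to-end analysis and return the results bundle
    (also written under ``outdir`` when given)."""
    cfg = config or synthetic_data.SimConfig(seed=seed)
    cfg.seed = seed
    outdir = Path(outdir) if outdir else None
    bundle: dict = {"schema_version": SCHEMA_VERSION, "seed": seed}

    # --- stage 1: generate inputs and round-trip them through the parser ---
    family = synthetic_data.simulate_gene_family(cfg, seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        paths = family.write(tmp)
        genes = gene_models.parse_gene_records(paths / "records.gbk")
        tables = gene_models.AnnotationTables.from_paths(
            signal_tsv=paths / "signal_calls.tsv",
            domain_tsv=paths / "domains.tsv",
            clade_txt=paths / "clade_leaves.txt",
            lifestyle_tsv=paths / "lifestyle.tsv",
            taxonomy_tsv=paths / "taxonomy.tsv",
        )
    genes, report = gene_models.attach_annotations(genes, tables)

    # --- stage 2: census and attribution ---
    census = as_census.build_census(genes)
    attribution = as_census.attribute_diversity(census)
    summary = as_census.clade_summary(census)
    species = as_census.species_summary(census)
    lifestyle = as_census.lifestyle_comparison(species)
    bundle["census"] = summary
    bundle["attribution"] = {
        "total_units": attribution.total_units,
        "as_units": attribution.as_units,
        "gd_units": attribution.gd_units,
        "domain_units": attribution.domain_units,
        "shares_pct": attribution.shares_pct(),
    }
    bundle["lifestyle_comparison"] = {
        k: v for k, v in lifestyle.items() if k != "metrics"
    } | {"metrics": {m: d for m, d in lifestyle["metrics"].items()}}

    # --- stage 3: splice anatomy ---
    offsets = splice_anatomy.splice_offset_distribution(
        [g for g in genes if g.domain_count == 1])
    bundle["splice_offsets"] = offsets.to_dict("records")

    # copy-number vs AS correlations, raw and phylogenetically corrected
    rho_pct = phylo_stats.spearman(species.copy_number.values,
                                   species.pct_as_genes.values)
    bundle["copy_number_vs_pct_as"] = _stat_dict(rho_pct)
    sp_tree = expansion_phylo.TaxonLabeledTree.from_newick(
        taxonomy_newick(family.taxonomy_table),
        family.taxonomy_table.set_index("species"))
    tree = phylo_stats.grafen_branch_lengths(sp_tree.tree)
    keyed = species.set_index(species.species.str.replace(" ", "_"))
    pic_x = phylo_stats.independent_contrasts(
        tree, keyed.copy_number.to_dict())
    pic_y = phylo_stats.independent_contrasts(
        tree, keyed.pct_as_genes.to_dict())
    bundle["pic_copy_number_vs_pct_as"] = _stat_dict(
        phylo_stats.correlation_through_origin(pic_x.contrasts, pic_y.contrasts))

    # --- stage 4: expansion levels and ancestral AS states ---
    gtree, _ = synthetic_data.simulate_labeled_tree(cfg, seed=seed, scale="gene")
    ranks = expansion_phylo.expansion_rank_table(gtree, scale="gene")
    bundle["gene_expansion"] = {
        "distributions": ranks["distributions"],
        "median_ranks": ranks.get("median_ranks"),
        "rank_test": _stat_dict(ranks["rank_test"]) if "rank_test" in ranks else None,
    }
    tip_values = {lf: float(np.random.default_rng((seed, 7)).poisson(3) + 1)
                  for lf in gtree.leaf_labels()}
    anc = expansion_phylo.ancestral_states_bm(gtree, tip_values)
    bundle["n_ancestral_nodes"] = len(anc)

    # --- stage 5: motif scanning and enrichment ---
    pwm = motif_regulation.make_pwm(DEFAULT_MOTIF_CONSENSUS, "dl_like")
    as_counts = {r.gene_id: r.c_as for r in family.truth.itertuples()
                 if r.domain_count == 1}
    seqs, annots, _truth = synthetic_data.simulate_regulatory_sequences(
        pwm, as_counts, cfg, seed=seed)
    as_ids = [g for g, c in as_counts.items() if c > 1]
    non_ids = [g for g, c in as_counts.items() if c == 1]
    if as_ids and non_ids:
        shuffled = [motif_regulation.shuffle_control(seqs[g], (seed, i))
                    for i, g in enumerate(as_ids)]
        enr = motif_regulation.enrichment_test(
            [seqs[g] for g in as_ids], shuffled, pwm, threshold=1e-4)
        bundle["motif_enrichment_vs_shuffled"] = asdict(enr)
    corr = motif_regulation.motif_as_correlation(seqs, as_counts, pwm, seed=seed)
    bundle["motif_as_correlation"] = {
        "real": _stat_dict(corr["real"]),
        "shuffled": _stat_dict(corr["shuffled"]) if "shuffled" in corr else None,
        "comparison": _stat_dict(corr["comparison"]) if "comparison" in corr else None,
    }

    # --- stage 6: exon-aware dN/dS ---
    pairs, _ = synthetic_data.simulate_codon_pairs(cfg, seed=seed)
    rates = [codon_evolution.pairwise_dnds(p["seq_a"], p["seq_b"],
                                           p["exon_id"], p["exon_class"])
             for p in pairs]
    bundle["dnds_comparison"] = codon_evolution.exon_class_comparison(rates)

    bundle["manifest"] = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "stages": ["simulate", "census", "splice", "expansion", "motifs",
                   "dnds", "stats"],
    }

    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        census.to_csv(outdir / "gene_census.tsv", sep="\t", index=False)
        species.to_csv(outdir / "species_summary.tsv", sep="\t", index=False)
        offsets.to_csv(outdir / "offsets.tsv", sep="\t", index=False)
        ranks["pairs"].to_csv(outdir / "expansion_pairs.tsv", sep="\t", index=False)
        (outdir / "results.json").write_text(
            json.dumps(bundle, indent=2, default=_json_default))
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    return str(obj)
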