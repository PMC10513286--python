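"""Parameter-recovery and calibration harnesses.

Each function reruns a pipeline stage on freshly generated synthetic data
many times and reports how often the planted structure is recovered — exact
truth equality for the census and expansion classifier, direction of effect
for the lifestyle, conservation, motif and dN/dS contrasts, and error-rate
calibration for the dependent-correlation test and the NG86 estimator.
"""

from __future__ import annotations

import math

import numpy as np

from . import (as_census, codon_evolution, expansion_phylo, motif_regulation,
               phylo_stats, splice_anatomy, synthetic_data)


def _child_seed(seed: int, stream: int, i: int) -> int:
    return int(np.random.default_rng((seed, stream, i)).integers(2 ** 31))


def census_exact_recovery(n_seeds: int = 50, seed: int = 0,
                          config=None) -> float:
    """Fraction of seeds for which the census equals the planted
    (n_as, c_as, domain_count) truth for every gene."""
    cfg = config or synthetic_data.SimConfig()
    hits = 0
    for i in range(n_seeds):
        fam = synthetic_data.simulate_gene_family(cfg, seed=_child_seed(seed, 1, i))
        census = as_census.build_census(fam.to_gene_models()).set_index("gene_id")
        ok = all(
            census.loc[r.gene_id, "n_as_count"] == r.n_as
            and census.loc[r.gene_id, "c_as_count"] == r.c_as
            and census.loc[r.gene_id, "domain_count"] == r.domain_count
            for r in fam.truth.itertuples()
        )
        hits += ok
    return hits / n_seeds


def expansion_exact_recovery(n_seeds: int = 50, seed: int = 0,
                             config=None) -> float:
    """Fraction of same-unit pairs (pooled over seeds) whose classified rank
    equals the planted rank."""
    cfg = config or synthetic_data.SimConfig()
    total = correct = 0
    for i in range(n_seeds):
        ttree, truth = synthetic_data.simulate_labeled_tree(
            cfg, seed=_child_seed(seed, 2, i))
        got = expansion_phylo.classify_all_pairs(ttree, "gene").set_index(
            ["leaf_a", "leaf_b"])["rank"]
        for r in truth.itertuples():
            total += 1
            correct += int(got.loc[(r.leaf_a, r.leaf_b)] == r.rank)
    return correct / total


def lifestyle_direction_recovery(n_runs: int = 200, seed: int = 0,
                                 config=None) -> dict:
    """Share of runs in which each lifestyle comparison recovers the planted
    direction: parasitoids higher on totals and copy number, lower on the
    AS percentage and mean AS count."""
    cfg = config or synthetic_data.SimConfig()
    signs = {"total_units": 1, "copy_number": 1, "pct_as_genes": -1,
             "mean_c_as": -1}
    hits = {k: 0 for k in signs}
    for i in range(n_runs):
        fam = synthetic_data.simulate_gene_family(cfg, seed=_child_seed(seed, 3, i))
        census = as_census.build_census(fam.to_gene_models())
        out = as_census.lifestyle_comparison(as_census.species_summary(census))
        for metric, sign in signs.items():
            if sign * out["metrics"][metric]["difference"] > 0:
                hits[metric] += 1
    return {k: v / n_runs for k, v in hits.items()}


def expansion_direction_recovery(n_runs: int = 200, seed: int = 0,
                                 config=None) -> float:
    """Share of runs in which parasitoid gene expansions come out more
    recent (lower median rank) than nonparasitoid ones."""
    cfg = config or synthetic_data.SimConfig()
    hits = 0
    for i in range(n_runs):
        ttree, _ = synthetic_data.simulate_labeled_tree(
            cfg, seed=_child_seed(seed, 4, i))
        out = expansion_phylo.expansion_rank_table(ttree, "gene")
        med = out["median_ranks"]
        hits += med["parasitoid"] < med["nonparasitoid"]
    return hits / n_runs


def conservation_direction_recovery(n_runs: int = 200, seed: int = 0,
                                    n_seqs: int = 20, length: int = 60,
                                    rate_as: float = 0.08,
                                    rate_non: float = 0.25) -> float:
    """Share of runs in which the constitutive-region conservation of an AS
    set evolved under a lower substitution rate exceeds the non-AS set under
    a paired signed-rank test (direction + significance)."""
    hits = 0
    for i in range(n_runs):
        aln_as, aln_non = synthetic_data.simulate_protein_alignments(
            n_seqs=n_seqs, length=length, rate_a=rate_as, rate_b=rate_non,
            seed=_child_seed(seed, 5, i))
        s_as = splice_anatomy.conservation_scores(aln_as)
        s_non = splice_anatomy.conservation_scores(aln_non)
        res = phylo_stats.wilcoxon_signed_rank(s_as, s_non)
        if np.median(s_as - s_non) > 0 and res.p_value < 0.05:
            hits += 1
    return hits / n_runs


def motif_correlation_recovery(n_runs: int = 200, seed: int = 0,
                               n_genes: int = 60, config=None) -> dict:
    """Planted motif copy number proportional to the AS count: share of runs
    with positive recovered Spearman rho, and share in which the real
    correlation significantly exceeds the shuffled baseline."""
    cfg = config or synthetic_data.SimConfig()
    pwm = motif_regulation.make_pwm("GGGAATTCCC", "dl_like")
    rho_pos = cmp_sig = 0
    for i in range(n_runs):
        s = _child_seed(seed, 6, i)
        rng = np.random.default_rng(s)
        counts = {f"g{j}": int(rng.integers(1, 9)) for j in range(n_genes)}
        seqs, _, _ = synthetic_data.simulate_regulatory_sequences(
            pwm, counts, cfg, seed=s)
        out = motif_regulation.motif_as_correlation(seqs, counts, pwm, seed=s)
        rho_pos += out["real"].defined and out["real"].statistic > 0
        cmp_sig += "comparison" in out and out["comparison"].p_value < 0.05
    return {"rho_positive": rho_pos / n_runs,
            "comparison_significant": cmp_sig / n_runs}


def motif_negative_control(n_runs: int = 200, seed: int = 0,
                           n_genes: int = 60, region: str = "promoter",
                           config=None) -> float:
    """Restricting the scan to a region without planted signal: share of
    runs in which the real-vs-shuffled comparison is NOT significant."""
    cfg = config or synthetic_data.SimConfig()
    pwm = motif_regulation.make_pwm("GGGAATTCCC", "dl_like")
    nulls = 0
    for i in range(n_runs):
        s = _child_seed(seed, 7, i)
        rng = np.random.default_rng(s)
        counts = {f"g{j}": int(rng.integers(1, 9)) for j in range(n_genes)}
        seqs, annots, _ = synthetic_data.simulate_regulatory_sequences(
            pwm, counts, cfg, seed=s)
        masks = {g: synthetic_data.mask_to_region(seqs[g], annots[g], region)
                 for g in seqs}
        out = motif_regulation.motif_as_correlation(
            seqs, counts, pwm, seed=s, annotation_masks=masks)
        if "comparison" not in out or out["comparison"].p_value >= 0.05:
            nulls += 1
    return nulls / n_runs


def dnds_direction_recovery(n_runs: int = 200, seed: int = 0,
                            config=None) -> float:
    """Share of runs in which alternative exons come out with a higher
    median dN/dS than constitutive exons."""
    cfg = config or synthetic_data.SimConfig()
    hits = 0
    for i in range(n_runs):
        pairs, _ = synthetic_data.simulate_codon_pairs(
            cfg, seed=_child_seed(seed, 8, i))
        rates = [codon_evolution.pairwise_dnds(p["seq_a"], p["seq_b"],
                                               p["exon_id"], p["exon_class"])
                 for p in pairs]
        out = codon_evolution.exon_class_comparison(rates)
        hits += (out["omega"]["alternative_median"]
                 > out["omega"]["constitutive_median"])
    return hits / n_runs


def hittner_type1_error(n_sims: int = 2000, seed: int = 0, n: int = 100,
                        alpha: float = 0.05) -> float:
    """Empirical type-I rate of the dependent-correlation comparison under a
    trivariate normal null with equal overlapping correlations."""
    rng = np.random.default_rng((seed, 9))
    cov = np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.2], [0.3, 0.2, 1.0]])
    chol = np.linalg.cholesky(cov)
    hits = 0
    for _ in range(n_sims):
        xyz = rng.normal(size=(n, 3)) @ chol.T
        r1 = phylo_stats.spearman(xyz[:, 0], xyz[:, 1]).statistic
        r2 = phylo_stats.spearman(xyz[:, 0], xyz[:, 2]).statistic
        r12 = phylo_stats.spearman(xyz[:, 1], xyz[:, 2]).statistic
        res = phylo_stats.compare_correlations(r1, r2, r12, n)
        hits += res.p_value < alpha
    return hits / n_sims


def ng86_neutral_calibration(n_reps: int = 200, seed: int = 0,
                             n_codons: int = 2000,
                             mutation_rate: float = 0.05) -> dict:
    """dN/dS of NG86 on pairs evolved with equal synonymous and
    nonsynonymous acceptance: mean over replicates with its standard
    error (should bracket 1 within 3 SE)."""
    cfg = synthetic_data.SimConfig(
        n_const_exons=1, n_alt_exons=0, const_exon_codons=n_codons,
        mutation_rate=mutation_rate,
        syn_accept={"constitutive": 1.0, "alternative": 1.0},
        nonsyn_accept={"constitutive": 1.0, "alternative": 1.0})
    omegas = []
    for i in range(n_reps):
        pairs, _ = synthetic_data.simulate_codon_pairs(
            cfg, seed=_child_seed(seed, 10, i))
        r = codon_evolution.pairwise_dnds(pairs[0]["seq_a"], pairs[0]["seq_b"])
        if r.omega is not None and not math.isnan(r.omega):
            omegas.append(r.omega)
    omegas = np.asarray(omegas)
    mean = float(omegas.mean())
    se = float(omegas.std(ddof=1) / math.sqrt(len(omegas)))
    return {"mean": mean, "se": se, "n": len(omegas)}
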