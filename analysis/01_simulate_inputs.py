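#!/usr/bin/env python
"""Generate the synthetic study inputs: a taxonomically structured serpin-like
gene family (GenBank + annotation tables + truth), labeled gene/exon trees
with planted expansion depths, and orthologous codon-pair exons.

Writes everything under results/inputs/ so the later stages can run from
files, the way the real pipeline consumes NCBI exports.
"""

import sys
from pathlib import Path

from serpinas import expansion_phylo, synthetic_data

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/inputs")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthetic_data.SimConfig(seed=SEED)

    family = synthetic_data.simulate_gene_family(cfg, seed=SEED)
    family.write(OUT)
    n_as = int((family.truth.c_as > 1).sum())
    print(f"gene family: {len(family.genes)} genes over "
          f"{family.taxonomy_table.species.nunique()} species; "
          f"{n_as} with C-terminal AS, "
          f"{int((family.truth.domain_count > 1).sum())} multi-domain")

    ttree, truth = synthetic_data.simulate_labeled_tree(cfg, seed=SEED)
    (OUT / "gene_tree.nwk").write_text(
        expansion_phylo.write_annotated_newick(ttree))
    ttree.metadata.to_csv(OUT / "gene_tree_metadata.tsv", sep="\t")
    truth.to_csv(OUT / "truth_expansion_ranks.tsv", sep="\t", index=False)
    print(f"labeled gene tree: {len(ttree.leaf_labels())} leaves, "
          f"{len(truth)} planted same-species pairs")

    pairs, ctruth = synthetic_data.simulate_codon_pairs(cfg, seed=SEED)
    with open(OUT / "codon_pairs.fasta", "w") as fh:
        for p in pairs:
            fh.write(f">{p['exon_id']}|{p['exon_class']}|a\n{p['seq_a']}\n")
            fh.write(f">{p['exon_id']}|{p['exon_class']}|b\n{p['seq_b']}\n")
    ctruth.to_csv(OUT / "truth_codon_counts.tsv", sep="\t", index=False)
    print(f"codon pairs: {len(pairs)} orthologous exons "
          f"({int((ctruth.exon_class == 'alternative').sum())} alternative)")


if __name__ == "__main__":
    main()
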