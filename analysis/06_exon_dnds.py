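#!/usr/bin/env python
"""Exon-aware NG86 dN/dS on the simulated orthologous exon pairs and the
constitutive vs alternative comparison.

Reads results/inputs/codon_pairs.fasta; writes results/dnds/.
"""

from pathlib import Path

from serpinas import codon_evolution as ce

IN = Path("results/inputs/codon_pairs.fasta")
OUT = Path("results/dnds")


def read_pairs(path):
    seqs = {}
    name = None
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            name = line[1:]
            seqs[name] = ""
        else:
            seqs[name] += line.strip()
    pairs = {}
    for name, seq in seqs.items():
        exon_id, cls, which = name.split("|")
        pairs.setdefault((exon_id, cls), {})[which] = seq
    return pairs


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rates = []
    for (exon_id, cls), pair in read_pairs(IN).items():
        rates.append(ce.pairwise_dnds(pair["a"], pair["b"], exon_id, cls))
    with open(OUT / "rates.tsv", "w") as fh:
        fh.write("exon_id\texon_class\tdN\tdS\tdNdS\n")
        for r in rates:
            omega = "" if r.omega is None else f"{r.omega:.4f}"
            fh.write(f"{r.exon_id}\t{r.exon_class}\t{r.dn:.4f}\t{r.ds:.4f}\t{omega}\n")
    out = ce.exon_class_comparison(rates)
    for metric, d in out.items():
        print(f"{metric}: constitutive median {d['constitutive_median']:.3f} "
              f"vs alternative {d['alternative_median']:.3f} "
              f"(W={d['W']:.0f}, p={d['p_value']:.3g})")


if __name__ == "__main__":
    main()
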