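"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure of the real data: serpin-like gene
models with constitutive exons and C-terminal alternative exons splicing just
after the hinge region (offset +1 with a leading G by default), mixed
signal-peptide N-termini, species-labeled gene/exon trees with duplications
planted at chosen taxonomic depths, intron-planted transcription-factor
motif instances whose copy number tracks the AS count, and codon pairs
evolved with class-specific synonymous/nonsynonymous regimes.  Default
parameters follow the direction of the real dataset: parasitoid species carry
more gene copies (more gene duplication) but less alternative splicing than
nonparasitoid species.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .codon_evolution import CODON_TABLE, STOP_CODONS, translate_codon
from .expansion_phylo import TaxonLabeledTree

HINGE = "GSEAAAVT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
# codons per amino acid, universal nuclear code
_CODONS_FOR = {}
for _c, _a in CODON_TABLE.items():
    if _a != "*":
        _CODONS_FOR.setdefault(_a, []).append(_c)
# junction residues whose codons can start with G (so the constitutive exon
# can end on the extra G)
_G_START = {aa: [c for c in cods if c[0] == "G"]
            for aa, cods in _CODONS_FOR.items()}
_G_START = {aa: cods for aa, cods in _G_START.items() if cods}


@dataclass
class LifestyleParams:
    """Per-lifestyle generative regime."""

    n_species: int = 8
    genes_per_species_mean: float = 6.0  # Poisson, floored at 1 (GD rate)
    p_c_as: float = 0.3  # probability a single-domain gene has C-terminal AS
    c_as_extra_mean: float = 4.0  # extra C-terminal forms beyond 1 (Poisson, >=1)
    p_domain_dup: float = 0.05
    p_n_as: float = 0.25  # probability of two N-terminal forms
    p_both_localization: float = 0.75  # given N-terminal AS


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline."""

    seed: int = 0
    # Parasitoids: strong gene-family expansion, sparse AS; nonparasitoids:
    # small families, frequent and deep AS.  Gene duplication dominates the
    # parasitoid unit budget, so per-species totals come out higher there.
    parasitoid: LifestyleParams = field(default_factory=lambda: LifestyleParams(
        n_species=8, genes_per_species_mean=15.0, p_c_as=0.10,
        c_as_extra_mean=2.0, p_domain_dup=0.10, p_n_as=0.15))
    nonparasitoid: LifestyleParams = field(default_factory=lambda: LifestyleParams(
        n_species=8, genes_per_species_mean=3.0, p_c_as=0.50,
        c_as_extra_mean=5.0, p_domain_dup=0.03, p_n_as=0.30))
    # hinge splice-offset distribution (offset -> probability)
    offset_probs: dict = field(default_factory=lambda: {1: 0.85, 4: 0.10, 7: 0.05})
    const_core_len: int = 60  # aa between N-terminal exon and hinge
    alt_region_len: int = 45  # aa per C-terminal alternative region
    intron_len: int = 60
    # regulatory sequences
    promoter_len: int = 300
    reg_exon_len: int = 150
    reg_intron_len: int = 350
    motif_rate_per_as: float = 0.8  # mean planted copies per unit of AS count
    # codon pair evolution
    n_const_exons: int = 6
    n_alt_exons: int = 16
    const_exon_codons: int = 60
    alt_exon_codons: int = 45
    mutation_rate: float = 0.12  # per-nucleotide proposal probability
    syn_accept: dict = field(default_factory=lambda: {
        "constitutive": 1.0, "alternative": 0.35})
    nonsyn_accept: dict = field(default_factory=lambda: {
        "constitutive": 0.15, "alternative": 0.9})
    # labeled trees
    blocks_per_lifestyle: int = 8
    rank_probs: dict = field(default_factory=lambda: {
        "parasitoid": (0.35, 0.35, 0.20, 0.05, 0.05),
        "nonparasitoid": (0.05, 0.10, 0.20, 0.35, 0.30)})

    def validate(self):
        for probs in (list(self.offset_probs.values()),
                      *[list(v) for v in self.rank_probs.values()]):
            arr = np.asarray(probs, dtype=float)
            if np.any(arr < 0) or not np.isclose(arr.sum(), 1.0):
                raise ValueError("probabilities must be in [0,1] and sum to 1")
        for ls in (self.parasitoid, self.nonparasitoid):
            for p in (ls.p_c_as, ls.p_domain_dup, ls.p_n_as, ls.p_both_localization):
                if not 0 <= p <= 1:
                    raise ValueError("probabilities must lie in [0, 1]")
        return self


# ---------------------------------------------------------------------------
# Sequence building blocks
# ---------------------------------------------------------------------------

def _random_protein(rng, length, start_met=False):
    aa = "".join(rng.choice(list(AA20), size=length))
    return ("M" + aa[1:]) if start_met else aa


def _reverse_translate(rng, protein):
    return "".join(rng.choice(_CODONS_FOR[a]) for a in protein)


def _random_intron(rng, length):
    mid = "".join(rng.choice(list("ACGT"), size=max(length - 4, 0)))
    return "GT" + mid + "AG"


@dataclass
class SyntheticGene:
    """One built gene: genomic sequence, per-isoform exon/CDS intervals and
    proteins, plus the planted truth."""

    gene_id: str
    species: str
    genome: str
    isoforms: list  # dicts: id, exon_intervals, cds_intervals, protein
    truth: dict
    intron_intervals: list = field(default_factory=list)
    promoter_interval: tuple | None = None


def build_synthetic_gene(gene_id: str, species: str, rng,
                         n_as: int = 1, c_as: int = 1, domain_count: int = 1,
                         offset: int = 1, localization: str = "extracellular",
                         config: SimConfig | None = None) -> SyntheticGene:
    """Construct one gene model with the requested planted census values.

    Multi-domain genes (domain_count > 1) are single-isoform, single-exon
    genes whose protein concatenates ``domain_count`` serpin-like units.
    AS genes carry ``n_as`` alternative first exons, two shared constitutive
    exons ending ``offset`` nucleotides after the hinge anchor (the last of
    which is a G, mirroring the G|GT donor), and ``c_as`` alternative
    C-terminal exons.
    """
    cfg = config or SimConfig()
    upstream = "".join(rng.choice(list("ACGT"), size=40))

    if domain_count > 1:
        unit = _random_protein(rng, 100)
        protein = "M" + (unit * domain_count)[1:]
        cds = _reverse_translate(rng, protein) + "TAA"
        genome = upstream + cds + "".join(rng.choice(list("ACGT"), size=20))
        start = len(upstream)
        iv = [(start, start + len(cds))]
        iso = dict(id=f"{gene_id}_p1", exon_intervals=iv, cds_intervals=iv,
                   protein=protein)
        truth = dict(gene_id=gene_id, species=species, n_as=1, c_as=1,
                     domain_count=domain_count, localization=localization,
                     offset=None)
        return SyntheticGene(gene_id, species, genome, [iso], truth)

    # N-terminal forms (alternative first exons), each a whole number of codons
    n_forms = []
    seen = set()
    while len(n_forms) < n_as:
        p = _random_protein(rng, 22, start_met=True)
        if p[:20] not in seen:
            seen.add(p[:20])
            n_forms.append(p)
    # constitutive body ending with the hinge motif
    body = _random_protein(rng, cfg.const_core_len) + HINGE
    # post-hinge constitutive tail: offset nucleotides, last one G (mirrors
    # the G|GT donor).  Complete codons inside the tail must not be stops.
    n_lead = offset - 1
    while True:
        tail_nt = "".join(rng.choice(list("ACGT"), size=n_lead)) + "G"
        full = [tail_nt[k:k + 3] for k in range(0, 3 * (offset // 3), 3)]
        if not any(c in STOP_CODONS for c in full):
            break
    # C-terminal alternative regions, distinct in their last 50 aa
    alt_prots = []
    seen_c = set()
    while len(alt_prots) < c_as:
        p = _random_protein(rng, cfg.alt_region_len)
        if p not in seen_c:
            seen_c.add(p)
            alt_prots.append(p)

    body_cds = _reverse_translate(rng, body)
    # split constitutive part into two exons at a codon boundary inside body
    n_cds_by_form = [_reverse_translate(rng, p) for p in n_forms]

    # alternative exon nucleotide payloads: completion of the junction codon
    # plus the alt region plus stop
    phase = (len(n_cds_by_form[0]) + len(body_cds) + offset) % 3
    completion_len = (3 - phase) % 3
    alt_payloads = []
    junction_res = []
    partial = tail_nt[3 * (offset // 3):]
    for p in alt_prots:
        while True:
            comp = "".join(rng.choice(list("ACGT"), size=completion_len))
            if not completion_len or (partial + comp) not in STOP_CODONS:
                break
        alt_payloads.append(comp + _reverse_translate(rng, p) + "TAA")
        junction_res.append(comp)

    # genomic assembly: upstream | exon1a [intron exon1b]* | intron | exon2
    # | intron | exon3(const tail) | (intron altexon_j)*
    pos = len(upstream)
    genome_parts = [upstream]
    exon1_iv = []
    for cds1 in n_cds_by_form:
        genome_parts.append(cds1)
        exon1_iv.append((pos, pos + len(cds1)))
        pos += len(cds1)
        intr = _random_intron(rng, cfg.intron_len)
        genome_parts.append(intr)
        pos += len(intr)
    split = 3 * (cfg.const_core_len // 2)
    exon2_seq = body_cds[:split]
    exon3_seq = body_cds[split:] + tail_nt
    exon2_iv = (pos, pos + len(exon2_seq))
    genome_parts.append(exon2_seq)
    pos += len(exon2_seq)
    intr = _random_intron(rng, cfg.intron_len)
    genome_parts.append(intr)
    pos += len(intr)
    exon3_iv = (pos, pos + len(exon3_seq))
    genome_parts.append(exon3_seq)
    pos += len(exon3_seq)
    alt_iv = []
    intron_iv = []
    for payload in alt_payloads:
        intr = _random_intron(rng, cfg.intron_len)
        genome_parts.append(intr)
        intron_iv.append((pos, pos + len(intr)))
        pos += len(intr)
        alt_iv.append((pos, pos + len(payload)))
        genome_parts.append(payload)
        pos += len(payload)
    genome_parts.append("".join(rng.choice(list("ACGT"), size=20)))
    genome = "".join(genome_parts)

    isoforms = []
    n_iso = max(n_as, c_as)
    for k in range(n_iso):
        ni = k % n_as
        cj = k % c_as
        ivs = [exon1_iv[ni], exon2_iv, exon3_iv, alt_iv[cj]]
        cds_seq = "".join(genome[s:e] for s, e in ivs)
        protein = str(Seq(cds_seq).translate()).rstrip("*")
        if "*" in protein:
            raise AssertionError("internal stop in synthetic CDS")
        isoforms.append(dict(
            id=f"{gene_id}_p{k + 1}", n_form=ni,
            exon_intervals=ivs, cds_intervals=ivs, protein=protein))
    truth = dict(gene_id=gene_id, species=species, n_as=n_as, c_as=c_as,
                 domain_count=1, localization=localization, offset=offset)
    return SyntheticGene(gene_id, species, genome, isoforms, truth,
                         intron_intervals=intron_iv,
                         promoter_interval=(0, len(upstream)))


# ---------------------------------------------------------------------------
# Family-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedFamily:
    genes: list  # SyntheticGene
    truth: pd.DataFrame
    signal_table: pd.DataFrame
    domain_table: pd.DataFrame
    lifestyle_table: pd.DataFrame
    taxonomy_table: pd.DataFrame
    clade_leaves: list

    def genbank_text(self) -> str:
        records = []
        for gene in self.genes:
            rec = SeqRecord(Seq(gene.genome), id=gene.gene_id,
                            name=gene.gene_id[:16],
                            description="synthetic serpin-like gene",
                            annotations={"molecule_type": "DNA",
                                         "organism": gene.species})
            rec.features.append(SeqFeature(
                FeatureLocation(0, len(gene.genome)), type="source",
                qualifiers={"organism": [gene.species]}))
            rec.features.append(SeqFeature(
                FeatureLocation(0, len(gene.genome)), type="gene",
                qualifiers={"gene": [gene.gene_id]}))
            for iso in gene.isoforms:
                loc = _compound(iso["exon_intervals"])
                rec.features.append(SeqFeature(loc, type="mRNA", qualifiers={
                    "gene": [gene.gene_id], "product": [iso["id"]]}))
                loc = _compound(iso["cds_intervals"])
                rec.features.append(SeqFeature(loc, type="CDS", qualifiers={
                    "gene": [gene.gene_id], "protein_id": [iso["id"]],
                    "translation": [iso["protein"]]}))
            records.append(rec)
        buf = io.StringIO()
        SeqIO.write(records, buf, "genbank")
        return buf.getvalue()

    def to_gene_models(self) -> list:
        """Build annotated :class:`~serpinas.gene_models.GeneModel` objects
        directly, equivalent to writing GenBank + tables and re-reading them
        (the file round-trip is exercised by its own tests)."""
        from .gene_models import GeneModel, Isoform

        signal = {r.protein_id: bool(r.has_signal_peptide)
                  for r in self.signal_table.itertuples()}
        taxonomy = {r.species: (r.genus, r.family, r.order)
                    for r in self.taxonomy_table.itertuples()}
        lifestyle = {r.species: r.lifestyle
                     for r in self.lifestyle_table.itertuples()}
        out = []
        for gene in self.genes:
            isoforms = [
                Isoform(id=iso["id"], exon_intervals=iso["exon_intervals"],
                        cds_intervals=iso["cds_intervals"],
                        protein=iso["protein"],
                        has_signal_peptide=signal.get(iso["id"]))
                for iso in gene.isoforms
            ]
            out.append(GeneModel(
                id=gene.gene_id, species=gene.species,
                taxonomy=taxonomy[gene.species],
                lifestyle=lifestyle[gene.species],
                isoforms=isoforms,
                domain_count=gene.truth["domain_count"],
                sequence=gene.genome))
        return out

    def write(self, outdir):
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "records.gbk").write_text(self.genbank_text())
        self.truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.signal_table.to_csv(outdir / "signal_calls.tsv", sep="\t", index=False)
        self.domain_table.to_csv(outdir / "domains.tsv", sep="\t", index=False)
        self.lifestyle_table.to_csv(outdir / "lifestyle.tsv", sep="\t", index=False)
        self.taxonomy_table.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        (outdir / "clade_leaves.txt").write_text(
            "\n".join(self.clade_leaves) + "\n")
        return outdir


def _compound(intervals):
    parts = [FeatureLocation(int(s), int(e), strand=1) for s, e in intervals]
    return parts[0] if len(parts) == 1 else CompoundLocation(parts)


def simulate_gene_family(config: SimConfig | None = None, seed=None
                         ) -> SimulatedFamily:
    """Generate a taxonomically structured gene family with planted AS, GD
    and domain-duplication structure plus every annotation table the census
    consumes."""
    cfg = (config or SimConfig()).validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    offsets = sorted(cfg.offset_probs)
    offset_p = np.array([cfg.offset_probs[o] for o in offsets])
    genes, truth_rows = [], []
    signal_rows, domain_rows, lifestyle_rows, taxonomy_rows = [], [], [], []
    gid = 0
    for lifestyle, params in (("parasitoid", cfg.parasitoid),
                              ("nonparasitoid", cfg.nonparasitoid)):
        for si in range(params.n_species):
            species = f"{lifestyle[:4].capitalize()}us species{si}"
            genus = f"{lifestyle[:4].capitalize()}us{si}"
            taxonomy_rows.append(dict(species=species, genus=genus,
                                      family=f"Fam_{lifestyle}_{si // 2}",
                                      order="Hymenoptera"))
            lifestyle_rows.append(dict(species=species, lifestyle=lifestyle))
            n_genes = max(1, int(rng.poisson(params.genes_per_species_mean)))
            for _ in range(n_genes):
                gid += 1
                gene_id = f"g{gid:04d}"
                if rng.random() < params.p_domain_dup:
                    dc = int(2 + rng.poisson(0.4))
                    g = build_synthetic_gene(gene_id, species, rng,
                                             domain_count=dc, config=cfg)
                else:
                    c_as = 1
                    if rng.random() < params.p_c_as:
                        c_as = 2 + int(rng.poisson(params.c_as_extra_mean - 1))
                    n_as = 2 if rng.random() < params.p_n_as else 1
                    if n_as > 1:
                        loc = ("both" if rng.random() < params.p_both_localization
                               else ("extracellular" if rng.random() < 0.5
                                     else "intracellular"))
                    else:
                        loc = ("extracellular" if rng.random() < 0.5
                               else "intracellular")
                    offset = int(rng.choice(offsets, p=offset_p))
                    g = build_synthetic_gene(
                        gene_id, species, rng, n_as=n_as, c_as=c_as,
                        offset=offset, localization=loc, config=cfg)
                genes.append(g)
                truth_rows.append({**g.truth, "lifestyle": lifestyle})
                # signal-peptide calls per isoform, consistent with planted
                # localization
                for iso in g.isoforms:
                    if g.truth["localization"] == "both":
                        call = iso.get("n_form", 0) == 0
                    else:
                        call = g.truth["localization"] == "extracellular"
                    signal_rows.append(dict(protein_id=iso["id"],
                                            has_signal_peptide=call))
                # domain intervals for every isoform protein
                dc = g.truth["domain_count"]
                for iso in g.isoforms:
                    plen = len(iso["protein"])
                    for d in range(dc):
                        domain_rows.append(dict(
                            protein_id=iso["id"],
                            start=d * (plen // dc),
                            end=(d + 1) * (plen // dc)))
    truth = pd.DataFrame(truth_rows)
    return SimulatedFamily(
        genes=genes,
        truth=truth,
        signal_table=pd.DataFrame(signal_rows),
        domain_table=pd.DataFrame(domain_rows),
        lifestyle_table=pd.DataFrame(lifestyle_rows),
        taxonomy_table=pd.DataFrame(taxonomy_rows),
        clade_leaves=truth.gene_id.tolist(),
    )


def _aa_code(j: int, width: int = 4) -> str:
    """Deterministic amino-acid encoding of an integer (base-20)."""
    out = []
    for _ in range(width):
        out.append(AA20[j % 20])
        j //= 20
    return "".join(out)


def build_reported_clade_census(n_as_genes: int = 192,
                                total_variants: int = 1406,
                                n_nonas: int = 494,
                                n_multidomain: int = 45,
                                total_domains: int = 105,
                                n_n_terminal_as: int = 153,
                                n_both_localization: int = 115,
                                n_any_terminal_as: int = 261,
                                offset_counts: dict | None = None) -> list:
    """Gene set reproducing the reported clade-level counts of the insect
    serpin C-terminal-AS clade (defaults: the 731-gene census with 192 AS
    genes / 1406 variants, 494 single-copy genes and 45 multi-domain genes
    with 105 domains).

    Variant and domain totals are spread as evenly as integers allow; the
    N-terminal-AS genes are distributed over the AS and non-AS sets so the
    any-terminal-AS total comes out exactly.  ``offset_counts`` (default
    161 x +1, 19 x +4, rest +7) plants the C-terminal splice offsets of the
    AS genes.  Returns minimal :class:`~serpinas.gene_models.GeneModel`
    objects sufficient for the census and splice-offset analyses.
    """
    from .gene_models import GeneModel, Isoform

    if offset_counts is None:
        offset_counts = {1: 161, 4: 19, 7: n_as_genes - 180}
    offsets = [o for o, c in sorted(offset_counts.items()) for _ in range(c)]
    if len(offsets) != n_as_genes:
        raise ValueError("offset counts must sum to the number of AS genes")
    n_overlap = n_n_terminal_as + n_as_genes - n_any_terminal_as
    if not 0 <= n_overlap <= min(n_n_terminal_as, n_as_genes):
        raise ValueError("inconsistent N-terminal/any-AS totals")
    # variants per AS gene: as even as possible, each >= 2
    base, extra = divmod(total_variants, n_as_genes)
    variants = [base + 1] * extra + [base] * (n_as_genes - extra)
    dbase, dextra = divmod(total_domains, n_multidomain)
    domains = [dbase + 1] * dextra + [dbase] * (n_multidomain - dextra)

    n_term_flags = ([True] * n_overlap + [False] * (n_as_genes - n_overlap)
                    + [True] * (n_n_terminal_as - n_overlap))
    both_budget = n_both_localization

    genes = []
    prefix = "MAAAAAAAAAA"  # shared first exon stub
    hinge_block = "LLLLLLLLLL" + HINGE  # single hinge match per protein
    gi = 0

    def n_keys(has_n_as):
        return [prefix + "K" * 10, "M" + "W" * 20] if has_n_as else [prefix + "K" * 10]

    for i in range(n_as_genes):
        gi += 1
        has_n = n_term_flags[i]
        heads = n_keys(has_n)
        isoforms = []
        for j in range(variants[i]):
            head = heads[j % len(heads)]
            tail = _aa_code(gi, 3) + _aa_code(j) + "G" * 43  # distinct last-50
            protein = head + hinge_block + tail
            anchor = 3 * (protein.index(HINGE) + len(HINGE)) - 1
            cut = anchor + offsets[i] + 1
            cds_len = 3 * len(protein) + 3
            isoforms.append(Isoform(
                id=f"ref{gi:04d}_p{j + 1}",
                exon_intervals=[(0, cut), (cut, cds_len)],
                cds_intervals=[(0, cut), (cut, cds_len)],
                protein=protein,
                has_signal_peptide=(j % len(heads) == 0) if has_n else True,
            ))
        if has_n and both_budget <= 0:
            for iso in isoforms:  # N-terminal AS but single localization
                iso.has_signal_peptide = True
        if has_n and both_budget > 0:
            both_budget -= 1
        genes.append(GeneModel(id=f"ref{gi:04d}", species="clade sp.",
                               isoforms=isoforms, domain_count=1))
    n_term_nonas = n_term_flags[n_as_genes:]
    for i in range(n_nonas):
        gi += 1
        has_n = i < len(n_term_nonas) and n_term_nonas[i]
        heads = n_keys(has_n)
        isoforms = [
            Isoform(id=f"ref{gi:04d}_p{k + 1}", exon_intervals=[],
                    cds_intervals=[], protein=h + hinge_block + _aa_code(gi) + "G" * 46,
                    has_signal_peptide=(k == 0) if has_n else True)
            for k, h in enumerate(heads)
        ]
        if has_n and both_budget > 0:
            both_budget -= 1
        elif has_n:
            for iso in isoforms:
                iso.has_signal_peptide = True
        genes.append(GeneModel(id=f"ref{gi:04d}", species="clade sp.",
                               isoforms=isoforms, domain_count=1))
    for i in range(n_multidomain):
        gi += 1
        protein = "M" + "D" * 40 + _aa_code(gi) + "E" * 40
        genes.append(GeneModel(
            id=f"ref{gi:04d}", species="clade sp.",
            isoforms=[Isoform(id=f"ref{gi:04d}_p1", exon_intervals=[],
                              cds_intervals=[], protein=protein,
                              has_signal_peptide=True)],
            domain_count=domains[i]))
    return genes


# ---------------------------------------------------------------------------
# Labeled trees with planted expansion depths
# ---------------------------------------------------------------------------

def simulate_labeled_tree(config: SimConfig | None = None, seed=None,
                          scale: str = "gene"):
    """A taxonomy-labeled tree built from blocks, each planting one same-unit
    pair whose expansion rank is chosen from the per-lifestyle rank
    distribution.  Returns (TaxonLabeledTree, truth DataFrame) where truth
    lists the planted rank of every same-unit pair."""
    cfg = (config or SimConfig()).validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    unit_key = "species" if scale == "gene" else "gene"
    blocks, meta_rows, truth_rows = [], [], []
    leaf_n = 0
    for lifestyle in ("parasitoid", "nonparasitoid"):
        probs = np.asarray(cfg.rank_probs[lifestyle], dtype=float)
        for b in range(cfg.blocks_per_lifestyle):
            rank = int(rng.choice(5, p=probs))
            tag = f"{lifestyle[:1]}{b}"
            # taxonomy of the pair's unit
            order = "Hymenoptera"
            family = f"F{tag}"
            genus = f"G{tag}"
            species = f"S{tag}a"
            gene = f"gene_{tag}_a"

            def leaf(unit_species, unit_genus, unit_family, unit_order,
                     unit_gene):
                nonlocal leaf_n
                leaf_n += 1
                label = f"L{leaf_n:03d}"
                meta_rows.append(dict(
                    leaf=label, gene=unit_gene, species=unit_species,
                    genus=unit_genus, family=unit_family, order=unit_order,
                    lifestyle=lifestyle))
                return label

            a = leaf(species, genus, family, order, gene)
            bb = leaf(species, genus, family, order, gene)
            if rank == 0:
                s = leaf(species, genus, family, order, gene)
            elif rank == 1:
                s = leaf(f"S{tag}b", genus, family, order, f"gene_{tag}_s")
            elif rank == 2:
                s = leaf(f"S{tag}s", f"G{tag}s", family, order, f"gene_{tag}_s")
            elif rank == 3:
                s = leaf(f"S{tag}s", f"G{tag}s", f"F{tag}s", order,
                         f"gene_{tag}_s")
            else:
                s = leaf(f"S{tag}s", f"G{tag}s", f"F{tag}s", "Diptera",
                         f"gene_{tag}_s")
            blocks.append(f"(({bb}:1,{s}:1):1,{a}:1)")
            truth_rows.append(dict(leaf_a=a, leaf_b=bb, rank=rank,
                                   lifestyle=lifestyle))
            if rank == 0:
                # the extra same-unit pairs created by a same-unit spreader
                truth_rows.append(dict(leaf_a=bb, leaf_b=s, rank=0,
                                       lifestyle=lifestyle))
                truth_rows.append(dict(leaf_a=a, leaf_b=s, rank=0,
                                       lifestyle=lifestyle))
    newick = blocks[0]
    for blk in blocks[1:]:
        newick = f"({newick}:1,{blk}:1)"
    newick += ";"
    metadata = pd.DataFrame(meta_rows).set_index("leaf")
    ttree = TaxonLabeledTree.from_newick(newick, metadata)
    truth = pd.DataFrame(truth_rows)
    return ttree, truth


# ---------------------------------------------------------------------------
# Regulatory sequences with planted motif instances
# ---------------------------------------------------------------------------

def simulate_regulatory_sequences(pwm, as_counts: dict,
                                  config: SimConfig | None = None, seed=None,
                                  plant_region: str = "intron",
                                  plant_strand: str = "+"):
    """Promoter/exon/intron gene sequences with motif-consensus instances
    planted in the chosen region, copy number Poisson with mean
    ``motif_rate_per_as * (c_as - 1)``.  Returns (sequences, annotations,
    truth DataFrame)."""
    from .motif_regulation import GeneRegionAnnotation, reverse_complement

    cfg = (config or SimConfig()).validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sequences, annotations = {}, {}
    truth_rows = []
    consensus = pwm.consensus
    for gene_id in sorted(as_counts):
        c_as = as_counts[gene_id]
        blocks = []
        parts = []
        pos = 0

        def add(length, label):
            nonlocal pos
            parts.append("".join(rng.choice(list("ACGT"), size=length)))
            blocks.append((pos, pos + length, label))
            pos += length

        add(cfg.promoter_len, "promoter")
        for i in range(3):
            add(cfg.reg_exon_len, "exon")
            if i < 2:
                add(cfg.reg_intron_len, "intron")
        seq = list("".join(parts))
        target_blocks = [b for b in blocks if b[2] == plant_region]
        n_plant = int(rng.poisson(cfg.motif_rate_per_as * max(c_as - 1, 0)))
        for _ in range(n_plant):
            s, e, _lab = target_blocks[int(rng.integers(len(target_blocks)))]
            if e - s < len(consensus) + 2:
                continue
            start = int(rng.integers(s + 1, e - len(consensus) - 1))
            word = consensus if plant_strand == "+" else reverse_complement(consensus)
            seq[start:start + len(consensus)] = list(word)
            truth_rows.append(dict(gene_id=gene_id, start=start,
                                   strand=plant_strand, region=plant_region))
        sequences[gene_id] = "".join(seq)
        annotations[gene_id] = GeneRegionAnnotation(blocks)
    truth = pd.DataFrame(truth_rows,
                         columns=["gene_id", "start", "strand", "region"])
    return sequences, annotations, truth


def mask_to_region(sequence: str, annotation, region: str, strand: str = "+"
                   ) -> str:
    """Mask everything outside one location class with N (strand handled by
    the caller's scan settings)."""
    seq = list("N" * len(sequence))
    for s, e, label in annotation.blocks:
        if label == region:
            seq[s:e] = sequence[s:e]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Codon pair evolution
# ---------------------------------------------------------------------------

def _evolve_codons(rng, codons, mu, syn_accept, nonsyn_accept):
    """One descendant of a codon sequence under per-nucleotide proposals with
    class-specific acceptance; returns (sequence, syn_count, nonsyn_count).

    Nonsense changes never occur: proposals are drawn uniformly among the
    viable (non-stop) alternative bases, so every position carries the same
    mutational opportunity — the convention the NG86 site counting assumes.
    """
    out = list(codons)
    syn = nonsyn = 0
    for i, codon in enumerate(out):
        codon = list(codon)
        for p in range(3):
            if rng.random() >= mu:
                continue
            old = codon[p]
            viable = []
            for b in "ACGT":
                if b == old:
                    continue
                cand = codon.copy()
                cand[p] = b
                if "".join(cand) not in STOP_CODONS:
                    viable.append(b)
            if not viable:
                continue
            cand = codon.copy()
            cand[p] = str(rng.choice(viable))
            if translate_codon("".join(cand)) == translate_codon("".join(codon)):
                if rng.random() < syn_accept:
                    codon = cand
                    syn += 1
            else:
                if rng.random() < nonsyn_accept:
                    codon = cand
                    nonsyn += 1
        out[i] = "".join(codon)
    return out, syn, nonsyn


def simulate_codon_pairs(config: SimConfig | None = None, seed=None):
    """Orthologous exon pairs evolved from common ancestors with
    class-specific synonymous/nonsynonymous regimes.  Returns (pairs, truth)
    where each pair is a dict with aligned codon sequences and truth holds
    the realized substitution counts per exon."""
    cfg = (config or SimConfig()).validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pairs, truth_rows = [], []
    plan = ([("constitutive", cfg.const_exon_codons)] * cfg.n_const_exons
            + [("alternative", cfg.alt_exon_codons)] * cfg.n_alt_exons)
    for i, (cls, n_codons) in enumerate(plan):
        ancestor = [str(rng.choice(_CODONS_FOR[a]))
                    for a in rng.choice(list(AA20), size=n_codons)]
        counts = {}
        seqs = {}
        for which in ("a", "b"):
            evolved, syn, nonsyn = _evolve_codons(
                rng, ancestor, cfg.mutation_rate,
                cfg.syn_accept[cls], cfg.nonsyn_accept[cls])
            seqs[which] = "".join(evolved)
            counts[which] = (syn, nonsyn)
        pairs.append(dict(exon_id=f"exon{i}", exon_class=cls,
                          seq_a=seqs["a"], seq_b=seqs["b"]))
        truth_rows.append(dict(
            exon_id=f"exon{i}", exon_class=cls,
            syn_a=counts["a"][0], nonsyn_a=counts["a"][1],
            syn_b=counts["b"][0], nonsyn_b=counts["b"][1]))
    return pairs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Protein alignments for the conservation contrast
# ---------------------------------------------------------------------------

def simulate_protein_alignments(n_seqs: int = 20, length: int = 60,
                                rate_a: float = 0.05, rate_b: float = 0.25,
                                seed=0):
    """Two gap-free alignments of the same length evolved from independent
    ancestors with different per-site substitution rates (set A lower by
    default), for paired per-column conservation comparisons."""
    rng = np.random.default_rng(seed)

    def make(rate):
        anc = _random_protein(rng, length)
        rows = []
        for _ in range(n_seqs):
            row = [
                (rng.choice(list(AA20)) if rng.random() < rate else ch)
                for ch in anc
            ]
            rows.append("".join(row))
        return rows

    return make(rate_a), make(rate_b)
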