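"""Gene/isoform data model and readers for GenBank records and annotation
tables.

Coordinates are 0-based half-open everywhere inside the package; 1-based
inclusive coordinates exist only at the GenBank I/O boundary (handled by
Biopython).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

N_TERM_LEN = 20
C_TERM_LEN = 50


def n_terminus_key(protein: str) -> str:
    """First 20 aa of a protein (whole protein if shorter)."""
    return protein[:N_TERM_LEN]


def c_terminus_key(protein: str) -> str:
    """Last 50 aa of a protein (whole protein if shorter)."""
    return protein[-C_TERM_LEN:]


@dataclass
class Isoform:
    id: str
    exon_intervals: list  # [(start, end)], 0-based half-open, genomic
    cds_intervals: list  # same convention
    protein: str
    has_signal_peptide: Optional[bool] = None
    codon_valid: bool = True  # False when CDS length % 3 != 0

    @property
    def n_terminus_key(self) -> str:
        return n_terminus_key(self.protein)

    @property
    def c_terminus_key(self) -> str:
        return c_terminus_key(self.protein)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_junctions(self) -> list:
        """CDS coordinates of the last nucleotide of each CDS segment except
        the final one, i.e. the exon/intron junction positions in spliced
        CDS space."""
        out, total = [], 0
        for s, e in self.cds_intervals[:-1]:
            total += e - s
            out.append(total - 1)
        return out


@dataclass
class GeneModel:
    id: str
    species: str = ""
    taxonomy: tuple = ("", "", "")  # (genus, family, order)
    lifestyle: str = "unknown"  # {parasitoid, nonparasitoid, unknown}
    isoforms: list = field(default_factory=list)
    domain_count: int = 1
    hinge_anchor: Optional[int] = None  # CDS coordinate of position 0
    in_clade: bool = True
    sequence: Optional[str] = None  # genomic sequence when available

    @property
    def genus(self) -> str:
        return self.taxonomy[0]

    def longest_isoform(self) -> Isoform:
        return max(self.isoforms, key=lambda iso: (len(iso.protein), iso.id))


@dataclass
class AnnotationTables:
    """Side tables consumed, not computed: signal-peptide calls, domain
    intervals, clade membership, lifestyle and taxonomy labels."""

    signal_calls: dict = field(default_factory=dict)  # protein id -> bool
    domain_table: dict = field(default_factory=dict)  # protein id -> [(s, e)]
    clade_leaves: set = field(default_factory=set)  # gene ids
    lifestyle_table: dict = field(default_factory=dict)  # species -> label
    taxonomy_table: dict = field(default_factory=dict)  # species -> (genus, family, order)

    @classmethod
    def from_paths(cls, signal_tsv=None, domain_tsv=None, clade_txt=None,
                   lifestyle_tsv=None, taxonomy_tsv=None) -> "AnnotationTables":
        tables = cls()
        if signal_tsv:
            df = pd.read_csv(signal_tsv, sep="\t")
            tables.signal_calls = {
                str(r.protein_id): bool(r.has_signal_peptide)
                for r in df.itertuples()
            }
        if domain_tsv:
            df = pd.read_csv(domain_tsv, sep="\t")
            for r in df.itertuples():
                tables.domain_table.setdefault(str(r.protein_id), []).append(
                    (int(r.start), int(r.end))
                )
        if clade_txt:
            with open(clade_txt) as fh:
                tables.clade_leaves = {ln.strip() for ln in fh if ln.strip()}
        if lifestyle_tsv:
            df = pd.read_csv(lifestyle_tsv, sep="\t")
            tables.lifestyle_table = {
                str(r.species): str(r.lifestyle) for r in df.itertuples()
            }
        if taxonomy_tsv:
            df = pd.read_csv(taxonomy_tsv, sep="\t")
            tables.taxonomy_table = {
                str(r.species): (str(r.genus), str(r.family), str(r.order))
                for r in df.itertuples()
            }
        return tables


class RecordParseError(ValueError):
    pass


def _feature_intervals(feature) -> list:
    """0-based half-open intervals of a (possibly compound) feature location,
    in transcription order."""
    parts = sorted(feature.location.parts, key=lambda p: int(p.start))
    if feature.location.strand == -1:
        parts = parts[::-1]
    return [(int(p.start), int(p.end)) for p in parts]


def parse_gene_records(path) -> list:
    """Parse a GenBank flat file into one :class:`GeneModel` per gene.

    Isoforms are grouped by the ``/gene`` qualifier within each record; mRNA
    features are paired with CDS features in order of appearance.  Protein
    translations are taken from the ``/translation`` qualifier and verified
    against the extracted CDS where the record carries sequence.  A CDS whose
    length is not a multiple of 3 is kept but flagged ``codon_valid=False``
    (excluded from codon-level operations only); isoforms lacking an
    annotated CDS are excluded with a warning.
    """
    genes: dict = {}
    n_records = n_skipped = 0
    for record in SeqIO.parse(str(path), "genbank"):
        n_records += 1
        species = record.annotations.get("organism", "")
        for feat in record.features:
            if feat.type == "source" and "organism" in feat.qualifiers:
                species = feat.qualifiers["organism"][0]
        mrnas: dict = {}
        for feat in record.features:
            if feat.type != "mRNA":
                continue
            gid = feat.qualifiers.get("gene", [record.id])[0]
            mrnas.setdefault(gid, []).append(feat)
        for feat in record.features:
            if feat.type != "CDS":
                continue
            gid = feat.qualifiers.get("gene", [record.id])[0]
            if "translation" not in feat.qualifiers:
                log.warning("record %s: CDS without translation skipped", record.id)
                n_skipped += 1
                continue
            protein = feat.qualifiers["translation"][0]
            try:
                cds_iv = _feature_intervals(feat)
            except Exception as exc:  # malformed coordinates
                raise RecordParseError(
                    f"record {record.id}: malformed CDS coordinates ({exc})"
                ) from exc
            iso_id = feat.qualifiers.get(
                "protein_id", [f"{record.id}_cds{len(genes.get(gid, GeneModel(gid)).isoforms)}"]
            )[0]
            gene = genes.setdefault(
                gid, GeneModel(id=gid, species=species, isoforms=[])
            )
            # pair with the next unconsumed mRNA of this gene, if any
            exon_iv = cds_iv
            pool = mrnas.get(gid, [])
            if len(gene.isoforms) < len(pool):
                exon_iv = _feature_intervals(pool[len(gene.isoforms)])
            cds_len = sum(e - s for s, e in cds_iv)
            codon_valid = cds_len % 3 == 0
            if not codon_valid:
                log.warning(
                    "record %s isoform %s: CDS length %d not a multiple of 3",
                    record.id, iso_id, cds_len,
                )
            if len(record.seq) and codon_valid:
                extracted = feat.location.extract(record.seq).translate()
                extracted = str(extracted).rstrip("*")
                if extracted != protein:
                    raise RecordParseError(
                        f"record {record.id} isoform {iso_id}: translation "
                        "does not round-trip from CDS"
                    )
            gene.isoforms.append(
                Isoform(
                    id=iso_id,
                    exon_intervals=exon_iv,
                    cds_intervals=cds_iv,
                    protein=protein,
                    codon_valid=codon_valid,
                )
            )
            if gene.sequence is None and len(record.seq):
                gene.sequence = str(record.seq)
    out = [g for g in genes.values() if g.isoforms]
    log.info("parsed %d records -> %d genes (%d CDS skipped)",
             n_records, len(out), n_skipped)
    return out


def attach_annotations(genes: Iterable[GeneModel], tables: AnnotationTables):
    """Attach signal calls, domain counts, lifestyle/taxonomy and clade
    membership.  Returns (genes, report) where the report lists ids that
    could not be resolved in each table (never silently dropped)."""
    report = {"signal_unmatched": [], "domain_unmatched": [],
              "lifestyle_unknown": [], "taxonomy_unmatched": []}
    genes = list(genes)
    for gene in genes:
        for iso in gene.isoforms:
            if iso.id in tables.signal_calls:
                iso.has_signal_peptide = tables.signal_calls[iso.id]
            else:
                report["signal_unmatched"].append(iso.id)
        longest = gene.longest_isoform()
        if longest.id in tables.domain_table:
            gene.domain_count = len(tables.domain_table[longest.id])
        else:
            report["domain_unmatched"].append(longest.id)
        if gene.species in tables.lifestyle_table:
            gene.lifestyle = tables.lifestyle_table[gene.species]
        else:
            gene.lifestyle = "unknown"
            report["lifestyle_unknown"].append(gene.species)
        if gene.species in tables.taxonomy_table:
            gene.taxonomy = tables.taxonomy_table[gene.species]
        else:
            report["taxonomy_unmatched"].append(gene.species)
        if tables.clade_leaves:
            gene.in_clade = gene.id in tables.clade_leaves
    for key, items in report.items():
        if items:
            log.warning("attach_annotations: %d %s", len(set(items)), key)
    return genes, report


def select_one_species_per_genus(genes: Iterable[GeneModel]) -> list:
    """Keep one species per genus to reduce sampling bias: the species with
    the most genes; ties broken by lexicographically smaller species name.
    Idempotent."""
    genes = list(genes)
    counts: dict = {}
    for g in genes:
        counts.setdefault(g.genus, {}).setdefault(g.species, 0)
        counts[g.genus][g.species] += 1
    keep = {}
    for genus, per_species in counts.items():
        best = sorted(per_species.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        keep[genus] = best
    return [g for g in genes if g.species == keep[g.genus]]
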