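"""Splice-site anatomy around the serpin hinge region.

Position 0 is the CDS coordinate of the last nucleotide at the end of the
hinge region (GSEAAAVT in the reference serpin); C-terminal splice offsets
are measured from it.  The module also builds position-frequency matrices
around splice sites, per-column conservation scores in bits, and maps scores
onto a reference protein's positions.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_models import GeneModel

log = logging.getLogger(__name__)

# Degenerate consensus for the hinge C-terminus; the literal instance in the
# reference gene is GSEAAAVT.
DEFAULT_HINGE_PATTERN = r"GSE[GA][GA][GA].[TSAV]"

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"


@dataclass
class SpliceEvent:
    gene_id: str
    isoform_id: str
    insertion_point: int  # CDS coordinate of the last nt before the intron
    offset: int  # insertion_point - hinge_anchor


@dataclass
class ConservationProfile:
    scores: np.ndarray  # per reference position, bits (NaN where undefined)
    reference_positions: np.ndarray  # 0-based positions in the reference
    region_labels: list  # "constitutive" / "alternative" per position
    reference_id: str = ""


def locate_hinge_anchor(gene: GeneModel, pattern: str = DEFAULT_HINGE_PATTERN):
    """CDS coordinate of the last nucleotide of the final hinge residue's
    codon in the longest isoform, or None when the pattern is absent
    (the gene is then excluded from offset analyses).  Multiple matches use
    the rightmost one, with a warning."""
    protein = gene.longest_isoform().protein
    matches = list(re.finditer(pattern, protein))
    if not matches:
        log.info("gene %s: hinge pattern not found; excluded from offsets", gene.id)
        return None
    if len(matches) > 1:
        log.warning("gene %s: %d hinge matches, using rightmost", gene.id, len(matches))
    m = matches[-1]
    return 3 * m.end() - 1


def gene_splice_events(gene: GeneModel, anchor=None) -> list:
    """C-terminal splice events per isoform: the last CDS junction of each
    multi-exon isoform, with its offset from the hinge anchor."""
    if anchor is None:
        anchor = gene.hinge_anchor
        if anchor is None:
            anchor = locate_hinge_anchor(gene)
    if anchor is None:
        return []
    events = []
    for iso in gene.isoforms:
        junctions = iso.cds_junctions()
        if not junctions:
            continue
        point = junctions[-1]
        events.append(
            SpliceEvent(gene.id, iso.id, point, point - anchor)
        )
    return events


def dominant_offset(gene: GeneModel, anchor=None):
    """Per-gene modal C-terminal splice offset across isoforms; ties are
    broken toward the smallest offset.  None when no event exists."""
    events = gene_splice_events(gene, anchor)
    if not events:
        return None
    tally = Counter(ev.offset for ev in events)
    best = max(tally.values())
    return min(o for o, c in tally.items() if c == best)


def splice_offset_distribution(genes, anchors=None) -> pd.DataFrame:
    """Integer histogram of per-gene dominant offsets with percentages of
    the total number of genes contributing an offset."""
    offsets = []
    for gene in genes:
        anchor = anchors.get(gene.id) if anchors else None
        off = dominant_offset(gene, anchor)
        if off is not None:
            offsets.append(off)
    tally = Counter(offsets)
    total = sum(tally.values())
    rows = [
        dict(offset=o, count=c, pct=100.0 * c / total)
        for o, c in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["offset", "count", "pct"])


# ---------------------------------------------------------------------------
# Logos and conservation
# ---------------------------------------------------------------------------

def splice_site_logo(contexts, alphabet: str = DNA_ALPHABET) -> pd.DataFrame:
    """Position-frequency count matrix from equal-anchored sequence windows.

    Windows may carry the padding marker '.' where they were truncated at a
    sequence end; padded cells do not contribute counts, so each column sums
    to the number of untruncated sequences at that position.
    """
    contexts = list(contexts)
    if not contexts:
        raise ValueError("empty context set")
    width = max(len(c) for c in contexts)
    counts = np.zeros((width, len(alphabet)), dtype=int)
    index = {a: i for i, a in enumerate(alphabet)}
    for ctx in contexts:
        for pos, letter in enumerate(ctx):
            if letter in index:
                counts[pos, index[letter]] += 1
    return pd.DataFrame(counts, columns=list(alphabet))


def logo_consensus(counts: pd.DataFrame) -> str:
    return "".join(counts.columns[i] for i in counts.values.argmax(axis=1))


def logo_column_tests(counts_a: pd.DataFrame, counts_b: pd.DataFrame):
    """Per-position chi-square comparing letter composition between two logo
    count matrices; returns a list of (chi2, p) per column."""
    from .phylo_stats import chi_square

    if counts_a.shape != counts_b.shape:
        raise ValueError("matrices must have identical shape")
    out = []
    for i in range(len(counts_a)):
        table = np.vstack([counts_a.values[i], counts_b.values[i]])
        keep = table.sum(axis=0) > 0
        res = chi_square(table[:, keep])
        out.append((res.statistic, res.p_value))
    return out


def conservation_scores(alignment, alphabet: str = PROTEIN_ALPHABET,
                        small_sample_correction: bool = False) -> np.ndarray:
    """Per-column conservation in bits: ``log2(A) - H(column)`` with gaps
    excluded from the frequencies.  The optional small-sample correction
    ``e = (A - 1) / (2 ln2 n)`` is subtracted (floored at 0).  All-gap
    columns are NaN."""
    rows = [str(r) for r in alignment]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows must have equal length")
    a_size = len(alphabet)
    max_bits = math.log2(a_size)
    length = len(rows[0])
    scores = np.full(length, np.nan)
    for j in range(length):
        col = [r[j] for r in rows if r[j] in alphabet]
        n = len(col)
        if n == 0:
            continue
        freqs = np.array(list(Counter(col).values()), dtype=float) / n
        entropy = float(-(freqs * np.log2(freqs)).sum())
        score = max_bits - entropy
        if small_sample_correction:
            score -= (a_size - 1) / (2.0 * math.log(2) * n)
        scores[j] = max(score, 0.0) if small_sample_correction else score
    return scores


def map_scores_to_reference(scores: np.ndarray, alignment: dict,
                            reference_id: str, hinge_end_ref_pos=None
                            ) -> ConservationProfile:
    """Drop alignment columns where the reference row has a gap and index the
    remaining scores by reference position.  Positions at or before
    ``hinge_end_ref_pos`` are labeled constitutive, later ones alternative
    (all constitutive when no hinge position is given)."""
    if reference_id not in alignment:
        raise KeyError(f"reference {reference_id!r} absent from alignment")
    ref_row = str(alignment[reference_id])
    if len(ref_row) != len(scores):
        raise ValueError("score vector does not match alignment length")
    cols = [j for j, ch in enumerate(ref_row) if ch != "-"]
    ref_positions = np.arange(len(cols))
    kept = scores[cols]
    if hinge_end_ref_pos is None:
        labels = ["constitutive"] * len(cols)
    else:
        labels = [
            "constitutive" if p <= hinge_end_ref_pos else "alternative"
            for p in ref_positions
        ]
    return ConservationProfile(kept, ref_positions, labels, reference_id)
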