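"""Exon-aware pairwise dN/dS by the Nei-Gojobori (1986) counting method.

Codons are assigned to exons by the majority-nucleotide rule (a codon
straddling a boundary belongs to the exon contributing more of its bases; a
1+1+1 split goes to the exon holding the middle base).  Synonymous and
nonsynonymous site fractions use the universal nuclear code with mutations to
stop codons disregarded; multi-difference codons average substitution counts
over all minimal pathways that avoid stop codons.  Proportions are corrected
with the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import pandas as pd

from .phylo_stats import mann_whitney_u

BASES = "TCAG"
CODON_TABLE = {}
for _b1 in BASES:
    for _b2 in BASES:
        for _b3 in BASES:
            CODON_TABLE[_b1 + _b2 + _b3] = None
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _codon in enumerate(CODON_TABLE):
    CODON_TABLE[_codon] = _AA[_i]
STOP_CODONS = {c for c, a in CODON_TABLE.items() if a == "*"}


def translate_codon(codon: str) -> str:
    return CODON_TABLE[codon.upper().replace("U", "T")]


@dataclass
class RatePair:
    exon_id: str
    exon_class: str  # constitutive / alternative / "" when unpartitioned
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    dn: float
    ds: float
    saturated: bool = False

    @property
    def omega(self):
        """dN/dS; None when dS == 0 (undefined)."""
        if self.ds == 0 or math.isnan(self.ds):
            return None
        return self.dn / self.ds


def assign_codons_to_exons(cds_length: int, boundaries) -> list:
    """Map each codon index to an exon index by majority base count.

    ``boundaries`` is a list of (start, end) intervals (0-based half-open in
    CDS coordinates) that must tile [0, cds_length).  Ties (1+1+1 splits) go
    to the exon containing the middle base.
    """
    boundaries = sorted((int(s), int(e)) for s, e in boundaries)
    pos = 0
    for s, e in boundaries:
        if s != pos or e <= s:
            raise ValueError("exon boundaries do not tile the CDS")
        pos = e
    if pos != cds_length:
        raise ValueError("exon boundaries do not tile the CDS")
    if cds_length % 3:
        raise ValueError("CDS length must be a multiple of 3")

    def exon_of(nt: int) -> int:
        for i, (s, e) in enumerate(boundaries):
            if s <= nt < e:
                return i
        raise AssertionError

    assignment = []
    for codon_idx in range(cds_length // 3):
        nts = [3 * codon_idx, 3 * codon_idx + 1, 3 * codon_idx + 2]
        exons = [exon_of(nt) for nt in nts]
        counts = {}
        for ex in exons:
            counts[ex] = counts.get(ex, 0) + 1
        best = max(counts.values())
        winners = [ex for ex, c in counts.items() if c == best]
        assignment.append(winners[0] if len(winners) == 1 else exons[1])
    return assignment


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str):
    """(synonymous, nonsynonymous) site counts for one codon as exact
    fractions summing to 3.  At each position the three alternative bases are
    considered; changes creating stop codons are disregarded."""
    codon = codon.upper()
    if codon in STOP_CODONS or any(b not in "TCAG" for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = CODON_TABLE[codon]
    s = Fraction(0)
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if CODON_TABLE[mutant] == aa:
                syn += 1
        if valid:
            s += Fraction(syn, valid)
    return s, 3 - s


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str):
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over all minimal substitution pathways that avoid stop codons
    (all pathways if every one passes through a stop)."""
    c1, c2 = c1.upper(), c2.upper()
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return Fraction(0), Fraction(0)

    def walk(order):
        cur = c1
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                hit_stop = True
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd, hit_stop

    results = [walk(order) for order in itertools.permutations(diff_pos)]
    clean = [(sd, nd) for sd, nd, stop in results if not stop]
    if not clean:
        clean = [(sd, nd) for sd, nd, _ in results]
    s = Fraction(sum(sd for sd, _ in clean), len(clean))
    n = Fraction(sum(nd for _, nd in clean), len(clean))
    return s, n


def _jc_correct(p: float):
    """Jukes-Cantor multiple-hit correction; returns (d, saturated)."""
    if p == 0:
        return 0.0, False
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def pairwise_dnds(seq1: str, seq2: str, exon_id: str = "",
                  exon_class: str = "") -> RatePair:
    """NG86 pairwise dN and dS on an aligned codon pair.

    Codon columns containing a gap in either sequence are dropped pairwise;
    internal stop codons are rejected.  Site counts are averaged between the
    two sequences; difference counts are pathway-averaged per codon.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be aligned with length % 3 == 0")
    s_sites = Fraction(0)
    s_diffs = Fraction(0)
    n_diffs = Fraction(0)
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if "-" in c1 or "-" in c2 or "N" in c1 or "N" in c2:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i // 3}")
        s1, _ = codon_site_fractions(c1)
        s2, _ = codon_site_fractions(c2)
        s_sites += (s1 + s2) / 2
        sd, nd = codon_pair_differences(c1, c2)
        s_diffs += sd
        n_diffs += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable (ungapped) codons in the overlap")
    n_sites = 3 * n_codons - s_sites
    ps = float(s_diffs / s_sites) if s_sites > 0 else 0.0
    pn = float(n_diffs / n_sites) if n_sites > 0 else 0.0
    ds, sat_s = _jc_correct(ps)
    dn, sat_n = _jc_correct(pn)
    return RatePair(
        exon_id=exon_id,
        exon_class=exon_class,
        n_sites=float(n_sites),
        s_sites=float(s_sites),
        n_diffs=float(n_diffs),
        s_diffs=float(s_diffs),
        dn=dn,
        ds=ds,
        saturated=sat_s or sat_n,
    )


def per_exon_dnds(seq1: str, seq2: str, boundaries, classes=None) -> list:
    """Partition an aligned codon pair into exons (majority rule on the
    ungapped CDS coordinates of the first sequence) and estimate NG86 rates
    per exon.  ``classes`` optionally maps exon index -> class label."""
    assignment = assign_codons_to_exons(len(seq1.replace("-", "")), boundaries)
    # walk alignment columns, tracking seq1 CDS position
    by_exon: dict = {}
    cds_pos = 0
    for col in range(0, len(seq1), 3):
        c1 = seq1[col:col + 3]
        c2 = seq2[col:col + 3]
        ungapped = c1.replace("-", "")
        if len(ungapped) == 3:
            exon = assignment[cds_pos // 3]
            if "-" not in c2:
                by_exon.setdefault(exon, ["", ""])
                by_exon[exon][0] += c1
                by_exon[exon][1] += c2
        cds_pos += len(ungapped)
    out = []
    for exon in sorted(by_exon):
        s1, s2 = by_exon[exon]
        label = classes.get(exon, "") if classes else ""
        out.append(pairwise_dnds(s1, s2, exon_id=str(exon), exon_class=label))
    return out


def exon_class_comparison(rate_pairs) -> dict:
    """Constitutive vs alternative exon comparison of dN, dS and dN/dS with
    two-sided rank-sum tests and per-class medians."""
    df = pd.DataFrame(
        [
            dict(exon_id=r.exon_id, exon_class=r.exon_class, dn=r.dn, ds=r.ds,
                 omega=(r.omega if r.omega is not None else math.nan))
            for r in rate_pairs
        ]
    )
    out = {}
    for cls in ("constitutive", "alternative"):
        if (df.exon_class == cls).sum() < 2:
            raise ValueError(f"exon class {cls!r} has fewer than 2 exons")
    for metric in ("dn", "ds", "omega"):
        alt = df.loc[df.exon_class == "alternative", metric].dropna().values
        con = df.loc[df.exon_class == "constitutive", metric].dropna().values
        test = mann_whitney_u(con, alt)
        out[metric] = {
            "constitutive_median": float(pd.Series(con).median()),
            "alternative_median": float(pd.Series(alt).median()),
            "W": test.statistic,
            "p_value": test.p_value,
        }
    return out
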