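"""PWM motif scanning with exact p-values, six-region hit categorization,
shuffled controls, enrichment tests and motif/AS-count correlations.

Scores are log-odds against a 0-order background, discretized onto an
integer grid (default: 1/1000 of the widest column's score range).  The null
score distribution is computed by dynamic programming over columns on that
grid, and both scanning and p-value lookup use the same integer scores, so
the reported p-value P(score >= observed) is exact on the grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from . import phylo_stats

log = logging.getLogger(__name__)

DNA = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_GRANULARITY = 1000
DEFAULT_PROMOTER_LEN = 2000


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


@dataclass
class PWMModel:
    """A position-frequency matrix with its background and the derived
    integer-grid log-odds representation."""

    motif_id: str
    pfm: np.ndarray  # (L, 4) column frequencies summing to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    granularity: int = DEFAULT_GRANULARITY

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 4:
            raise ValueError("PFM must be (L, 4)")
        if not np.allclose(self.pfm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PFM columns must sum to 1")
        if np.any(self.background <= 0):
            raise ValueError("background must be strictly positive")
        counts = self.pfm + self.pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        probs = np.clip(probs, 1e-10, None)  # keep log-odds finite
        self.log_odds = np.log2(probs / self.background)
        # integer grid: step = 1/granularity of the widest per-column range
        ranges = self.log_odds.max(axis=1) - self.log_odds.min(axis=1)
        self.grid_step = max(ranges.max(), 1e-12) / self.granularity
        self.int_scores = np.round(self.log_odds / self.grid_step).astype(np.int64)
        self._pvalue_cache = None

    def __len__(self) -> int:
        return self.pfm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.pfm.argmax(axis=1))


def make_pwm(consensus: str, motif_id: str = "motif",
             dominance: float = 0.85, background=None) -> PWMModel:
    """PWM with ``dominance`` probability on the consensus base at each
    column and the remainder spread uniformly."""
    pfm = np.full((len(consensus), 4), (1.0 - dominance) / 3.0)
    for i, b in enumerate(consensus.upper()):
        pfm[i, DNA.index(b)] = dominance
    kw = {"background": np.asarray(background, dtype=float)} if background is not None else {}
    return PWMModel(motif_id, pfm, **kw)


def parse_meme_motifs(text_or_path) -> list:
    """Read PWMs from MEME minimal motif format text (or a file path)."""
    try:
        text = open(text_or_path).read()
    except (OSError, TypeError):
        text = str(text_or_path)
    background = np.full(4, 0.25)
    motifs = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            rows = []
            i += 1
            while i < len(lines):
                s = lines[i].strip()
                if s.startswith("letter-probability matrix") or not s:
                    i += 1
                    continue
                fields = s.split()
                if len(fields) == 4 and all(_is_float(f) for f in fields):
                    rows.append([float(f) for f in fields])
                    i += 1
                else:
                    break
            pfm = np.array(rows)
            pfm = pfm / pfm.sum(axis=1, keepdims=True)  # renormalize rounding
            motifs.append(PWMModel(motif_id, pfm, background.copy()))
            continue
        i += 1
    return motifs


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_meme_motifs(motifs, background=None) -> str:
    bg = background if background is not None else np.full(4, 0.25)
    out = ["MEME version 4", "", "ALPHABET= ACGT", "",
           "Background letter frequencies",
           f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}", ""]
    for m in motifs:
        out.append(f"MOTIF {m.motif_id}")
        out.append(
            f"letter-probability matrix: alength= 4 w= {len(m)} nsites= 20 E= 0")
        for row in m.pfm:
            out.append(" ".join(f"{v:.6f}" for v in row))
        out.append("")
    return "\n".join(out)


def score_pvalue_table(pwm: PWMModel):
    """Exact null distribution of the integer grid score by DP over columns.

    Returns (offset, pmf, survival) where ``survival[k]`` is
    P(int score >= k + offset) under the background; total mass 1 +- 1e-9.
    """
    if pwm._pvalue_cache is not None:
        return pwm._pvalue_cache
    ints = pwm.int_scores - pwm.int_scores.min(axis=1, keepdims=True)
    shift = int(pwm.int_scores.min(axis=1).sum())
    width = int(ints.max(axis=1).sum()) + 1
    pmf = np.zeros(width)
    pmf[0] = 1.0
    reach = 1
    for col in range(len(pwm)):
        new = np.zeros(width)
        for letter in range(4):
            s = int(ints[col, letter])
            new[s:s + reach] += pwm.background[letter] * pmf[:reach]
        reach += int(ints[col].max())
        pmf = new
    survival = np.cumsum(pmf[::-1])[::-1]
    pwm._pvalue_cache = (shift, pmf, survival)
    return pwm._pvalue_cache


def pvalue_of_int_score(pwm: PWMModel, int_score: int) -> float:
    shift, _, survival = score_pvalue_table(pwm)
    k = int(int_score) - shift
    if k < 0:
        return 1.0
    if k >= len(survival):
        return float(survival[-1])
    return float(survival[k])


@dataclass
class MotifHit:
    sequence_id: str
    motif_id: str
    start: int  # 0-based on the forward strand
    strand: str  # "+" or "-"
    score: float
    int_score: int
    p_value: float
    region: Optional[tuple] = None  # (location, strand class)
    found: bool = True


_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(DNA):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_int_scores(pwm: PWMModel, enc: np.ndarray) -> np.ndarray:
    """Integer scores of all windows; windows containing non-ACGT get the
    sentinel minimum (never best)."""
    L = len(pwm)
    n = len(enc) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = pwm.int_scores[np.arange(L), safe].sum(axis=1)
    scores[~valid] = np.iinfo(np.int64).min
    return scores


def best_hit(pwm: PWMModel, sequence: str, sequence_id: str = "",
             strands: str = "+-") -> MotifHit:
    """Best (minimal exact p-value) hit over all positions and the requested
    strands; ties break to the smallest forward-strand start, then to '+'.
    Returns a no-hit record when the sequence is shorter than the motif."""
    if len(sequence) < len(pwm):
        return MotifHit(sequence_id, pwm.motif_id, -1, "+", math.nan,
                        0, math.nan, found=False)
    enc = _encode(sequence)
    candidates = []  # (int_score negated later) -> pick max score
    if "+" in strands:
        fwd = _window_int_scores(pwm, enc)
        candidates.append(("+", fwd))
    if "-" in strands:
        rc = _encode(reverse_complement(sequence))
        rev = _window_int_scores(pwm, rc)
        # map reverse-complement window i to forward start
        n = len(rev)
        remapped = rev[::-1]  # rc window i covers forward start n-1-i
        candidates.append(("-", remapped))
    best = None  # (-(int_score), start, strand_order)
    for strand, scores in candidates:
        if scores.size == 0:
            continue
        order = 0 if strand == "+" else 1
        i = int(np.argmax(scores))
        top = int(scores[i])
        starts = np.flatnonzero(scores == top)
        start = int(starts[0])
        key = (-top, start, order)
        if best is None or key < best[0]:
            best = (key, strand, start, top)
    if best is None or best[3] == np.iinfo(np.int64).min:
        return MotifHit(sequence_id, pwm.motif_id, -1, "+", math.nan,
                        0, math.nan, found=False)
    _, strand, start, int_score = best
    if strand == "+":
        window = sequence[start:start + len(pwm)].upper()
    else:
        window = reverse_complement(sequence[start:start + len(pwm)].upper())
    float_score = float(
        sum(pwm.log_odds[i, DNA.index(b)] for i, b in enumerate(window))
    )
    return MotifHit(sequence_id, pwm.motif_id, start, strand, float_score,
                    int_score, pvalue_of_int_score(pwm, int_score))


@dataclass
class GeneRegionAnnotation:
    """Block structure of a scanned gene sequence: promoter / exon / intron
    intervals (0-based half-open in scanned-sequence coordinates)."""

    blocks: list  # [(start, end, label)] with label in {promoter, exon, intron}

    def span(self) -> tuple:
        return self.blocks[0][0], self.blocks[-1][1]


def categorize_region(hit: MotifHit, annotation: GeneRegionAnnotation,
                      motif_length: int) -> tuple:
    """(location, strand class) of a hit: location by majority overlap of the
    hit interval with the annotation blocks, ties to the upstream-most class;
    strand '+' is the coding strand."""
    lo, hi = hit.start, hit.start + motif_length
    s0, s1 = annotation.span()
    if lo < s0 or hi > s1:
        raise ValueError("hit outside the annotated span")
    overlap: dict = {}
    first_seen: dict = {}
    for start, end, label in annotation.blocks:
        ov = max(0, min(hi, end) - max(lo, start))
        if ov > 0:
            overlap[label] = overlap.get(label, 0) + ov
            first_seen.setdefault(label, start)
    best = max(overlap.values())
    winners = [lab for lab, ov in overlap.items() if ov == best]
    location = min(winners, key=lambda lab: first_seen[lab])
    strand_class = "coding" if hit.strand == "+" else "noncoding"
    return (location, strand_class)


def shuffle_control(sequence: str, seed) -> str:
    """Mononucleotide shuffle preserving the exact letter multiset;
    deterministic per seed.  Masked positions (non-ACGT, e.g. 'N') stay in
    place so region-restricted scans keep their geometry."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    idx = np.flatnonzero(_ENC[arr] >= 0)
    arr[idx] = arr[rng.permutation(idx)]
    return arr.tobytes().decode()


@dataclass
class EnrichmentResult:
    motif_id: str
    primary_hits: int
    primary_n: int
    control_hits: int
    control_n: int
    enrichment_ratio: float
    test: str  # "fisher" or "binomial"
    p_value: float


def enrichment_test(primary, control, pwm: PWMModel, threshold: float = 0.05,
                    length_tolerance: float = 1e-4) -> EnrichmentResult:
    """Motif enrichment of the primary set over the control set.

    A sequence "has" the motif when its best-hit p-value is <= threshold.
    Fisher's exact test (one-sided, enrichment) when the two sets have the
    same average length within ``length_tolerance`` (relative); otherwise a
    binomial test with the control-derived success probability (Laplace
    smoothed to stay inside (0, 1)).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    primary, control = list(primary), list(control)
    if not primary or not control:
        raise ValueError("both sequence sets must be non-empty")

    def n_with(seqs):
        return sum(
            1 for s in seqs
            if (h := best_hit(pwm, s)).found and h.p_value <= threshold
        )

    k1, n1 = n_with(primary), len(primary)
    k2, n2 = n_with(control), len(control)
    f1 = k1 / n1
    f2 = k2 / n2
    ratio = f1 / f2 if f2 > 0 else math.inf if f1 > 0 else 1.0
    mean1 = sum(map(len, primary)) / n1
    mean2 = sum(map(len, control)) / n2
    same_length = abs(mean1 - mean2) <= length_tolerance * max(mean1, mean2)
    if same_length:
        _, p = sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]],
                                alternative="greater")
        test = "fisher"
    else:
        p0 = (k2 + 1) / (n2 + 2)
        p = float(sps.binomtest(k1, n1, p0, alternative="greater").pvalue)
        test = "binomial"
    return EnrichmentResult(pwm.motif_id, k1, n1, k2, n2, ratio, test, float(p))


def presence_score(pwm: PWMModel, sequence: str) -> float:
    """-log10 of the best-hit p-value (0 when no hit is possible)."""
    hit = best_hit(pwm, sequence)
    if not hit.found:
        return 0.0
    return -math.log10(max(hit.p_value, 1e-300))


def motif_as_correlation(sequences: dict, as_counts: dict, pwm: PWMModel,
                         seed: int = 0, annotation_masks: dict | None = None
                         ) -> dict:
    """Spearman correlation between per-gene motif presence scores
    (-log10 best-hit p) and C-terminal AS counts, with a paired baseline
    from per-gene mononucleotide shuffles and a dependent-correlation
    comparison (shared variable: the AS count).

    ``annotation_masks`` optionally maps gene id -> masked sequence
    restricting the scan to one region category.
    """
    gene_ids = sorted(set(sequences) & set(as_counts))
    if len(gene_ids) < 5:
        raise ValueError("need >= 5 genes with sequences and AS counts")
    seqs = {g: (annotation_masks[g] if annotation_masks else sequences[g])
            for g in gene_ids}
    counts = np.array([as_counts[g] for g in gene_ids], dtype=float)
    if np.all(counts == counts[0]):
        return {"real": phylo_stats.StatResult(
            "rho", math.nan, math.nan, len(gene_ids), defined=False,
            note="constant AS counts")}
    real = np.array([presence_score(pwm, seqs[g]) for g in gene_ids])
    shuffled = np.array([
        presence_score(pwm, shuffle_control(seqs[g], (seed, i)))
        for i, g in enumerate(gene_ids)
    ])
    res_real = phylo_stats.spearman(counts, real)
    res_shuf = phylo_stats.spearman(counts, shuffled)
    out = {"real": res_real, "shuffled": res_shuf,
           "real_scores": real, "shuffled_scores": shuffled}
    if res_real.defined and res_shuf.defined:
        r12 = phylo_stats.spearman(real, shuffled).statistic
        if abs(r12) < 1 and abs(res_real.statistic) < 1 and abs(res_shuf.statistic) < 1:
            out["comparison"] = phylo_stats.compare_correlations(
                res_real.statistic, res_shuf.statistic, r12, len(gene_ids))
    return out
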