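# Methods

This package implements a comparative analysis of how three evolutionary
processes — alternative splicing (AS), gene duplication (GD) and intragenic
domain duplication — generate protein diversity in an insect serpin gene
clade, together with a synthetic data generator that produces every input
with known ground truth. This note documents the models, the conventions and
defaults, the numerical choices, and what the synthetic benchmarks do and do
not establish.

## Isoform census and diversity attribution

AS event counts are operational: the number of N-terminal AS forms of a gene
is the number of distinct first-20-aa sequences among its isoform proteins,
and the number of C-terminal AS forms is the number of distinct last-50-aa
sequences. Proteins shorter than the window contribute the whole protein as
their key; such genes remain countable. Trailing stop codons are trimmed
before any protein-length check.

Genes are partitioned into three sets: **AS** (single serpin domain, more
than one C-terminal form), **multi-domain** (more than one serpin domain),
and **non-AS** (one domain, one C-terminal form), the last taken to have
arisen by gene duplication. The two non-trivial sets are mutually exclusive
in the real clade; a gene claiming both C-terminal AS and multiple domains
fails validation loudly instead of being silently reassigned.

Diversity attribution uses exact integer bookkeeping of "protein/domain
units": an AS gene contributes its count of C-terminal forms, a multi-domain
gene its domain count, a non-AS gene one unit. On the reported clade
composition (192 AS genes with 1406 variants, 494 non-AS genes, 45
multi-domain genes with 105 domains) this yields 2005 units split
70.1% / 24.6% / 5.2%. Percentages are reported at one decimal with half-up
rounding. The clade's N-terminal-AS share computes to 20.9% (153/731); the
package reports computed values throughout.

Localization classes come from signal-peptide calls consumed as a table
(never predicted in-repo): a gene is *both* extra- and intracellular when
its distinct N-terminal forms carry mixed calls.

One-species-per-genus subsampling keeps the species with the most census
genes per genus, ties broken by lexicographically smaller species name. The
subsampling goal is fixed by the study design; the concrete rule is this
package's choice and is deterministic and idempotent.

## Splice-site anatomy

Coordinates are 0-based half-open everywhere; 1-based inclusive coordinates
exist only at the GenBank boundary. Position 0 of a gene is the CDS
coordinate of the last nucleotide of the final hinge-region codon of its
longest isoform. The hinge is located with a degenerate pattern
(`GSE[GA][GA][GA].[TSAV]`, matching the canonical GSEAAAVT instance),
user-overridable; with multiple matches the rightmost is used, and genes
without a match are excluded from offset analyses with a log record.

A C-terminal splice event is an isoform's last exon/exon junction in CDS
coordinates; its offset is the junction coordinate minus the anchor. Each
gene is counted once, at its modal offset over isoforms (ties go to the
smaller offset); an any-isoform counting mode exists behind a flag.

Conservation per alignment column is `log2(A) − H` in bits, where `H` is the
Shannon entropy of residue frequencies with gaps excluded (not a 21st
symbol) and `A` the alphabet size (20 for protein). The small-sample
correction `(A−1)/(2·ln2·n)` is off by default and available by flag.
Scores are mapped to a reference row by dropping columns gapped in the
reference; the constitutive/alternative region split falls at the hinge-end
reference position.

## Expansion levels on taxonomy-labeled trees

For a pair of leaves, the expansion level is the lowest taxonomic rank
shared by *all* leaves under their most recent common ancestor. Gene-scale
pairs (two genes of one species) use the ladder species(0) < genus(1) <
family(2) < order(3) < not-specific(4); exon-scale pairs (two alternative
exons of one gene) use gene(0) < genus(1) < family(2) < order(3) <
not-specific(4). The exon ladder has no species rung — any same-species,
different-gene clade member already implies the genus rung. Every same-unit
pair is enumerated, not only cherries. Rank distributions are compared
between lifestyles with a two-sided rank-sum test plus per-rank 2×2
chi-square tests.

Ancestral states of the C-terminal AS count are maximum-likelihood Brownian
motion estimates, computed as the joint generalized-least-squares optimum —
the internal values minimizing Σ (child − parent)² / branch length — which
for each node equals the re-rooted weighted-average estimate. Zero-length
branches are perturbed by 1e-8 with a warning.

## Motif scanning and enrichment

PWMs are position-frequency matrices (MEME minimal format supported) with a
pseudocount of 0.1 per cell and log-odds against a 0-order background.
Scores are discretized onto an integer grid whose step is 1/1000 of the
widest per-column score range; the null distribution of the integer score is
computed exactly by dynamic programming over columns, and scanning uses the
same integer scores, so p-values are exact on the grid (the brute-force
4^L enumeration agrees to 1e-12 for L ≤ 8). Best hits minimize the exact
p-value over positions and strands, ties to the smaller start and then the
`+` strand. Windows containing non-ACGT letters never score, which is also
how region-restricted scans are implemented (masking with N).

Hits fall into six region categories: {promoter, exon, intron} × {coding,
noncoding strand}. Location is decided by majority overlap, ties to the
upstream-most class. Promoters are approximated by upstream sequence of the
translation start (default 2000 nt in real data; the synthetic generator
uses 300 nt to keep benchmarks small). Shuffled controls are exact
mononucleotide permutations, deterministic per seed, with masked positions
held in place.

Set-level enrichment follows the simple-enrichment rule: a sequence has the
motif when its best-hit p-value is below the threshold; Fisher's one-sided
exact test when primary and control mean lengths agree within 0.01%,
otherwise a binomial test with Laplace-smoothed control rate. Per-gene motif
presence for correlations is −log10 of the best-hit p-value (the raw
p-value is also emitted); its Spearman correlation with the C-terminal AS
count is compared against a paired shuffled baseline with the
dependent-correlation z test below.

## Exon-aware dN/dS

Codons are assigned to exons by the majority-base rule: a codon straddling a
boundary belongs to the exon contributing more of its three bases; a 1+1+1
split goes to the exon holding the middle base.

Pairwise rates use the Nei–Gojobori (1986) counting method rather than a
maximum-likelihood codon model — a deliberate method substitution; the
analysis surface is the qualitative constitutive-vs-alternative contrast,
not absolute rate values. Synonymous site fractions are computed per codon
position as synonymous changes over viable changes (mutations to stop codons
disregarded), so S + N = 3 per codon exactly (rational arithmetic).
Multi-difference codons average substitution counts over all minimal
pathways avoiding stop codons (all pathways if none avoids them). Gapped
codon columns are dropped pairwise; internal stops are an error. Proportions
are Jukes–Cantor corrected, `d = −(3/4)·ln(1 − 4p/3)`; p ≥ 3/4 is flagged
saturated rather than extrapolated. dN/dS is undefined (flagged) when
dS = 0. The universal nuclear code is fixed.

## Statistics layer

Rank-sum and signed-rank tests enumerate exactly (handling ties) up to a
combined n of 12 and use tie-corrected normal approximations above; Spearman
uses exact permutation up to n = 10 and the t-approximation beyond.
Chi-square is the plain Pearson r×c form without continuity correction.
Correlations of independent contrasts go through the origin,
`r = Σxy/√(Σx²Σy²)`, with p from t on n−1 df.

Independent contrasts follow Felsenstein's pruning with branch-length
augmentation `v₁v₂/(v₁+v₂)`; polytomies are resolved arbitrarily to
near-zero branches with a warning. Grafen branch lengths set node height to
(number of descendant leaves − 1)^ρ normalized to root height 1 (ρ = 1 by
default; ρ ≤ 0 warns).

Dependent overlapping correlations (two correlations sharing one variable)
are compared with the back-transformed-average z procedure: Fisher-z of both
correlations, their average back-transformed and plugged into Dunn & Clark's
covariance term, two-sided normal p. Its type-I error calibrates to
0.03–0.07 at α = 0.05 over 2000 trivariate-normal null simulations (n = 100),
run by the acceptance suite.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions and are not tuned per analysis.

*Gene families.* Two lifestyles with contrasting regimes: parasitoids get
large families (Poisson mean 15 genes/species), sparse C-terminal AS
(p = 0.10, mean ≈ 3 forms per AS gene) and more domain duplication
(p = 0.10); nonparasitoids get small families (mean 3), frequent and deep AS
(p = 0.50, mean ≈ 6 forms) and little domain duplication (p = 0.03). These
magnitudes mirror the direction of the real lifestyle contrasts — gene
duplication dominates the parasitoid unit budget — at desk scale (8 species
per lifestyle by default). Each AS gene has alternative first exons
(N-terminal forms as whole codons), two constitutive body exons whose last
nucleotide is a G placed `offset` nucleotides after the hinge anchor
(offset +1 with probability 0.85, +4 with 0.10, +7 with 0.05), and one
C-terminal alternative exon per planted form with distinct last-50-aa.
Introns are GT…AG. Records are emitted as genuinely parseable GenBank
(LOCUS/FEATURES/ORIGIN with mRNA/CDS joins and translations), so the real
parser path is exercised; signal-peptide calls, domain intervals, lifestyle
and taxonomy ship as the side tables the census consumes.

*Labeled trees.* Trees are assembled from blocks, each planting one
same-unit pair plus a "spreader" leaf whose taxonomic distance fixes the
pair's expansion rank; pair units are unique across blocks so the planted
pairs are exactly the enumerable same-unit pairs. Parasitoid blocks draw
mostly low (recent) ranks, nonparasitoid blocks mostly high ranks.

*Regulatory sequences.* Promoter/exon/intron layouts with motif-consensus
copies planted in introns on the coding strand, copy number Poisson with
mean 0.8 per unit of (AS count − 1), over a uniform background. A REL-family
(NF-κB-like) consensus GGGAATTCCC stands in for the dorsal/Dif matrices.

*Codon pairs.* Orthologous exons evolve from common ancestors under
per-nucleotide proposals (rate 0.12 per site per branch) drawn uniformly
among viable (non-stop) alternatives, with class-specific acceptance:
constitutive exons accept synonymous changes fully and nonsynonymous at
0.15; alternative exons accept synonymous at 0.35 and nonsynonymous at 0.9 —
planting the observed higher-dN, lower-dS, higher-dN/dS alternative-exon
signature. Drawing proposals among viable bases gives every position equal
mutational opportunity, the convention the NG86 site counting assumes; the
neutral calibration (both acceptances 1, 2000 codons, rate 0.05, 200
replicates) brackets mean dN/dS = 1 within 3 standard errors. Shorter
neutral sequences would not: the mean of ratios carries an upward
Jensen-type bias of order CV(dS)², which the calibration length keeps well
below the Monte Carlo error.

*What the benchmarks show.* Recovery tests demonstrate that each stage
inverts its generator: the census reproduces planted counts exactly, the
classifier recovers planted ranks, and each direction-of-effect harness
recovers its planted contrast in ≥95% of 200 runs (≥90% for the
real-vs-shuffled motif comparison and the null-region negative control).
They do not establish robustness to features the generator omits: alignment
error, incomplete isoform catalogs (real AS counts are transcriptome-depth
dependent), unequal base composition, rate variation among sites,
non-GT/AG introns, or biased tree inference. The clade-arithmetic fixtures
validate bookkeeping on the reported composition, not re-derivation of that
composition from raw sequence databases.

## Problem sizes and determinism

Default benchmark sizes (8+8 species, ~150 genes, 16-block trees, 60-gene
motif panels, 22 exon pairs, 200-run recovery sweeps, 2000 null
simulations) were chosen so the whole suite runs in a few minutes on one
CPU. All randomness flows through `numpy.random.default_rng` seeded from
explicit arguments; a fixed seed regenerates byte-identical GenBank text and
identical downstream results.

## Known limitations

- NG86 is a counting estimator: no transition/transversion or codon-usage
  weighting, and saturation (p ≥ 3/4) is flagged, not modeled.
- The exact PWM p-values are exact on the score grid; competing hits whose
  float scores differ by less than one grid step tie on the grid.
- Expansion classification trusts the input topology; there is no support
  filtering, and overlapping pairs are all counted (an experimental
  MRCA-deduplication option is noted in the interface but off).
- The dependent-correlation z test treats rank correlations like product-
  moment ones, as in common practice; its calibration here is empirical.
- `lifestyle_comparison` and the contrasts operate per species; within-genus
  pseudo-replication is addressed only by the one-species-per-genus filter.
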