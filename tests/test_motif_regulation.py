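"""PWM scanning, exact p-values, region categories, shuffles, enrichment."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from serpinas import motif_regulation as mr


@pytest.fixture(scope="module")
def pwm():
    return mr.make_pwm("GGGAATTCCC", "dl_like")


def brute_force_distribution(pwm):
    """Oracle: enumerate all 4^L words, sum background probabilities by
    integer score."""
    dist = {}
    for word in itertools.product(range(4), repeat=len(pwm)):
        score = int(pwm.int_scores[np.arange(len(pwm)), list(word)].sum())
        prob = float(np.prod(pwm.background[list(word)]))
        dist[score] = dist.get(score, 0.0) + prob
    return dist


class TestExactPValues:
    def test_length_one_certain_letter(self):
        pfm = np.array([[1.0, 0.0, 0.0, 0.0]])
        pwm1 = mr.PWMModel("m1", pfm, pseudocount=0.0)
        shift, pmf, survival = mr.score_pvalue_table(pwm1)
        # max score is achieved only by the certain letter: p = 0.25
        assert mr.pvalue_of_int_score(pwm1, pwm1.int_scores[0].max()) == pytest.approx(0.25)

    @pytest.mark.parametrize("consensus", ["GGGAATTC", "ACGT", "TTTTTT"])
    def test_dp_equals_enumeration(self, consensus):
        pwm = mr.make_pwm(consensus, "t", dominance=0.7,
                          background=[0.3, 0.2, 0.2, 0.3])
        oracle = brute_force_distribution(pwm)
        total = sum(oracle.values())
        assert total == pytest.approx(1.0, abs=1e-9)
        for score in sorted(oracle):
            tail = sum(p for s, p in oracle.items() if s >= score)
            assert mr.pvalue_of_int_score(pwm, score) == pytest.approx(
                tail, abs=1e-12)

    def test_grid_refinement_stays_within_rounding_bound(self):
        """Doubling the grid resolution moves no window p-value beyond the
        rounding bound implied by the coarser grid."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        coarse = mr.make_pwm("GGGAATTCCC", "c", dominance=0.8)
        fine = mr.make_pwm("GGGAATTCCC", "f", dominance=0.8)
        fine.granularity = coarse.granularity * 2
        fine.__post_init__()
        hc = mr.best_hit(coarse, seq)
        hf = mr.best_hit(fine, seq)
        assert (hc.start, hc.strand) == (hf.start, hf.strand)
        # p-values computed on the two grids agree closely
        assert math.log10(hc.p_value) == pytest.approx(
            math.log10(hf.p_value), abs=0.1)

    def test_total_mass_one(self, pwm):
        _, pmf, _ = mr.score_pvalue_table(pwm)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)


class TestBestHit:
    def test_consensus_sequence_hits_at_zero(self, pwm):
        hit = mr.best_hit(pwm, pwm.consensus)
        assert (hit.start, hit.strand) == (0, "+")
        assert hit.p_value == pytest.approx(
            mr.pvalue_of_int_score(pwm, pwm.int_scores.max(axis=1).sum()))

    def test_reverse_strand_plant(self, rng):
        asym = mr.make_pwm("GGGGATTTCC", "asym")  # not its own complement
        bg = "".join(rng.choice(list("AT"), size=60))
        seq = bg + mr.reverse_complement(asym.consensus) + bg
        hit = mr.best_hit(asym, seq)
        assert hit.strand == "-"
        assert hit.start == 60

    def test_matches_brute_force_argmin(self, pwm, rng):
        for _ in range(8):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            hit = mr.best_hit(pwm, seq)
            best = None
            L = len(pwm)
            for strand in "+-":
                for start in range(len(seq) - L + 1):
                    word = seq[start:start + L]
                    if strand == "-":
                        word = mr.reverse_complement(word)
                    s = sum(pwm.int_scores[i, "ACGT".index(b)]
                            for i, b in enumerate(word))
                    key = (-s, start, strand)
                    if best is None or key < best:
                        best = key
            assert (-best[0], best[1], best[2]) == (hit.int_score, hit.start,
                                                    hit.strand)

    def test_short_sequence_no_hit(self, pwm):
        hit = mr.best_hit(pwm, "ACG")
        assert not hit.found

    def test_pvalue_invariant_under_reverse_complement(self, pwm, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            h1 = mr.best_hit(pwm, seq)
            h2 = mr.best_hit(pwm, mr.reverse_complement(seq))
            assert h1.p_value == pytest.approx(h2.p_value)


class TestRegions:
    annotation = mr.GeneRegionAnnotation(
        [(0, 100, "promoter"), (100, 200, "exon"), (200, 300, "intron"),
         (300, 400, "exon")])

    def hit(self, start, strand="+"):
        return mr.MotifHit("s", "m", start, strand, 0.0, 0, 0.5)

    def test_inside_intron_coding_strand(self):
        assert mr.categorize_region(self.hit(250), self.annotation, 10) == (
            "intron", "coding")

    def test_promoter_hit(self):
        assert mr.categorize_region(self.hit(5, "-"), self.annotation, 10) == (
            "promoter", "noncoding")

    def test_majority_overlap_rule(self):
        # 4 nt in exon [196,200), 6 nt in intron [200,206) -> intron
        assert mr.categorize_region(self.hit(196), self.annotation, 10) == (
            "intron", "coding")

    def test_tie_goes_upstream(self):
        assert mr.categorize_region(self.hit(195), self.annotation, 10) == (
            "exon", "coding")

    def test_outside_span_raises(self):
        with pytest.raises(ValueError):
            mr.categorize_region(self.hit(395), self.annotation, 10)


class TestShuffle:
    def test_homopolymer_unchanged(self):
        assert mr.shuffle_control("AAAAAA", 1) == "AAAAAA"

    def test_composition_preserved_and_deterministic(self, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGTN"), size=100))
            s1 = mr.shuffle_control(seq, 42)
            s2 = mr.shuffle_control(seq, 42)
            s3 = mr.shuffle_control(seq, 43)
            assert s1 == s2
            assert sorted(s1) == sorted(seq)
            # masked letters stay in place
            assert [i for i, b in enumerate(seq) if b == "N"] == [
                i for i, b in enumerate(s1) if b == "N"]
            if len(set(seq)) > 2:
                assert s3 != s1


class TestEnrichment:
    def test_identical_sets_are_null(self, pwm, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(15)]
        res = mr.enrichment_test(seqs, list(seqs), pwm, threshold=0.01)
        assert res.enrichment_ratio == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_fisher_branch_equals_hypergeometric_tail(self, pwm, rng):
        """On a fixed-size 2x2 table the Fisher branch reproduces the
        hypergeometric tail computed directly."""
        planted = [pwm.consensus + "".join(rng.choice(list("ACGT"), size=90))
                   for _ in range(8)]
        clean = ["".join(rng.choice(list("AT"), size=100)) for _ in range(12)]
        primary = planted + clean[:2]
        control = clean[2:] + planted[:0]
        res = mr.enrichment_test(primary, control, pwm, threshold=1e-5)
        k1, n1, k2, n2 = (res.primary_hits, res.primary_n,
                          res.control_hits, res.control_n)
        tail = sps.hypergeom.sf(k1 - 1, n1 + n2, k1 + k2, n1)
        assert res.test == "fisher"
        assert res.p_value == pytest.approx(float(tail))

    def test_binomial_branch_on_unequal_lengths(self, pwm, rng):
        primary = [pwm.consensus + "".join(rng.choice(list("ACGT"), size=200))
                   for _ in range(10)]
        control = ["".join(rng.choice(list("ACGT"), size=60))
                   for _ in range(10)]
        res = mr.enrichment_test(primary, control, pwm, threshold=1e-4)
        assert res.test == "binomial"
        assert res.p_value < 0.01

    def test_bad_threshold_rejected(self, pwm):
        with pytest.raises(ValueError):
            mr.enrichment_test(["ACGT"], ["ACGT"], pwm, threshold=0.0)


class TestCorrelation:
    def test_constant_counts_reported_undefined(self, pwm, rng):
        seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), size=100))
                for i in range(6)}
        out = mr.motif_as_correlation(seqs, {g: 3 for g in seqs}, pwm)
        assert not out["real"].defined

    def test_planted_copy_number_recovers_positive_rho(self, pwm, rng):
        from serpinas import synthetic_data as sd
        counts = {f"g{i}": int(rng.integers(1, 9)) for i in range(40)}
        seqs, _, _ = sd.simulate_regulatory_sequences(pwm, counts, seed=9)
        out = mr.motif_as_correlation(seqs, counts, pwm, seed=9)
        assert out["real"].statistic > 0
        assert out["real"].p_value < 0.05
        assert out["comparison"].p_value < 0.05
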