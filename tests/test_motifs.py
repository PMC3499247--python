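"""PWM construction and the motif / gapped-consensus scanners."""

import math

import numpy as np
import pytest

from snapcall import motifs
from snapcall.utils import IUPAC, revcomp


def pwm_scan_oracle(seq, pwm, both_strands=True):
    """Brute-force per-position probability-product scores (log2 vs uniform)."""
    out = []
    L = len(pwm)
    for off in range(len(seq) - L + 1):
        for strand in ("+", "-") if both_strands else ("+",):
            site = seq[off:off + L] if strand == "+" else \
                revcomp(seq[off:off + L])
            prod, ok = 1.0, True
            for j, b in enumerate(site):
                if b not in "ACGT":
                    ok = False
                    break
                prod *= pwm.matrix[j, "ACGT".index(b)] / 0.25
            if ok:
                out.append((off, strand, math.log2(prod)))
    return out


def consensus_scan_oracle(seq, cons, max_mm):
    out = []
    L = len(cons)
    for off in range(len(seq) - L + 1):
        for strand in ("+", "-"):
            site = seq[off:off + L] if strand == "+" else \
                revcomp(seq[off:off + L])
            mm = sum(b not in IUPAC.get(c, "") for c, b in zip(cons, site))
            if mm <= max_mm:
                out.append((off, strand, mm))
    return out


class TestBuildPwm:
    def test_identical_sites_near_delta_columns(self):
        pwm = motifs.build_pwm(["ACGT"] * 25)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)
        ic = pwm.info_content()
        assert (ic > 1.5).all() and (ic < 2.0).all()  # pseudocount-attenuated
        assert pwm.consensus() == "ACGT"

    def test_two_site_mixture_entropy(self):
        pwm = motifs.build_pwm(["AAAA", "TTTT"], pseudocount=1e-9)
        assert np.allclose(pwm.matrix[:, 0], 0.5, atol=1e-6)
        assert np.allclose(pwm.info_content(), 1.0, atol=1e-5)

    def test_column_normalization_on_random_alignments(self):
        rng = np.random.default_rng(0)
        sites = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(9)]
        pwm = motifs.build_pwm(sites)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_ragged_alignment_raises(self):
        with pytest.raises(ValueError, match="ragged"):
            motifs.build_pwm(["ACGT", "ACG"])

    def test_single_site_raises(self):
        with pytest.raises(ValueError):
            motifs.build_pwm(["ACGTAC"])


class TestScanPwm:
    def _pwm(self):
        return motifs.build_pwm(["TTAACGGC"] * 5)

    def test_planted_consensus_is_top_hit(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 60))
        seq = seq[:20] + "TTAACGGC" + seq[28:]
        hits = motifs.scan_pwm(seq, self._pwm())
        assert hits[0].offset == 20 and hits[0].strand == "+"

    def test_reverse_complement_hit_on_minus_strand(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 60))
        seq = seq[:20] + revcomp("TTAACGGC") + seq[28:]
        hits = motifs.scan_pwm(seq, self._pwm())
        assert hits[0].offset == 20 and hits[0].strand == "-"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 50))
        pwm = motifs.build_pwm(
            ["".join(rng.choice(list("ACGT"), 6)) for _ in range(4)])
        hits = motifs.scan_pwm(seq, pwm, score_floor=-1e9)
        oracle = consensus = pwm_scan_oracle(seq, pwm)
        got = {(h.offset, h.strand): h.score for h in hits}
        assert len(got) == len(oracle)
        for off, strand, score in oracle:
            assert got[(off, strand)] == pytest.approx(score, abs=1e-9)

    def test_n_runs_yield_no_hits(self):
        hits = motifs.scan_pwm("NNNNNNNNNNNN", self._pwm(), score_floor=-1e9)
        assert hits == []


class TestScanConsensus:
    def test_exact_octamer_found(self):
        seq = "GCGC" + "ATGCAAAT" + "GGCC"
        hits = motifs.scan_consensus(seq, "ATGCAAAT")
        assert hits[0].offset == 4 and hits[0].mismatches == 0

    def test_two_mismatch_rule(self):
        """Two mismatches still match; three do not."""
        seq = "GCGC" + "ATGCAACC" + "GGCC"          # 2 mismatches
        assert motifs.scan_consensus(seq, "ATGCAAAT", 2)
        seq3 = "GCGC" + "ATGGAACC" + "GGCC"         # 3 mismatches
        plus_hits = [h for h in motifs.scan_consensus(seq3, "ATGCAAAT", 2)
                     if h.strand == "+" and h.offset == 4]
        assert plus_hits == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        hits = motifs.scan_consensus(seq, "ATGCAAAT", 2)
        oracle = consensus_scan_oracle(seq, "ATGCAAAT", 2)
        assert {(h.offset, h.strand, h.mismatches) for h in hits} \
            == set(oracle)


class TestGappedConsensus:
    def test_invalid_gap_bounds(self):
        with pytest.raises(ValueError):
            motifs.GappedConsensus("GTTT", 4, 1, "AANARNAGA")

    @pytest.mark.parametrize("gap", [1, 2, 3, 4])
    def test_all_gap_lengths_found(self, gap):
        rng = np.random.default_rng(gap)
        flank = "".join(rng.choice(list("CT"), 40))  # cannot contain GTTT
        planted = "GTTT" + "C" * gap + "AATAAGAGA"
        seq = flank[:11] + planted + flank[11:]
        hits = motifs.scan_3prime_box(seq, window=len(seq))
        assert hits and hits[0].offset == 11 and hits[0].gap == gap

    def test_box_at_plus_12(self):
        seq = "C" * 11 + "GTTTC" + "AATAA" + "A" + "AGA" + "C" * 90
        hits = motifs.scan_3prime_box(seq)
        # offset 11 -> position +12 in 1-based flank coordinates
        assert hits[0].offset + 1 == 12

    def test_no_conforming_sequence_empty(self):
        assert motifs.scan_3prime_box("C" * 100) == []

    def test_matches_substring_enumeration(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 300))
        hits = motifs.scan_gapped(seq, motifs.BOX3_CONSENSUS, max_mismatch=1)
        # oracle: enumerate every (offset, gap) placement directly
        expected = set()
        for gap in range(1, 5):
            pat = "GTTT" + "N" * gap + "AANARNAGA"
            for off in range(len(seq) - len(pat) + 1):
                mm = sum(b not in IUPAC[c]
                         for c, b in zip(pat, seq[off:off + len(pat)]))
                if mm <= 1:
                    expected.add((off, gap, mm))
        assert {(h.offset, h.gap, h.mismatches) for h in hits} == expected


class TestAnnotatePromoter:
    def _genome(self, promoter, downstream="G" * 120):
        rng = np.random.default_rng(3)
        left = "".join(rng.choice(list("ACGT"), 200))
        gene = "".join(rng.choice(list("ACGT"), 100))
        return {"chr1": left + promoter + gene + downstream}, 200 + len(promoter)

    def test_closest_motif_to_summit_is_occupied(self):
        """Two planted octamers; the one nearer the peak summit wins."""
        promoter = ("C" * 50 + "ATGCAAAT" + "C" * 100 + "ATGCAAAT"
                    + "C" * 84)
        genome, tss = self._genome(promoter)
        up1 = -(len(promoter) - 50)        # upstream octamer start
        up2 = -(len(promoter) - 158)       # downstream octamer start
        summit_near_downstream = tss + up2 + 4
        arch = motifs.annotate_promoter(
            "L", genome, "chr1", tss, "+",
            element_set={"OCT": "ATGCAAAT"},
            activator_summits={"POU2F1": [("chr1", summit_near_downstream)]},
            upstream=250)
        oct_hits = [e for e in arch.entries if e.element == "OCT"
                    and e.mismatches == 0]
        by_pos = {e.start_rel: e.occupied for e in oct_hits}
        assert by_pos[up2] is True
        assert by_pos[up1] is False

    def test_no_peak_means_crossed_out(self):
        promoter = "C" * 100 + "ATGCAAAT" + "C" * 100
        genome, tss = self._genome(promoter)
        arch = motifs.annotate_promoter(
            "L", genome, "chr1", tss, "+",
            element_set={"OCT": "ATGCAAAT"}, activator_summits={},
            upstream=200)
        assert all(e.occupied is False for e in arch.entries
                   if e.element == "OCT")

    def test_basal_elements_reported_without_occupancy(self):
        promoter = ("C" * 30 + motifs.CANONICAL_ELEMENTS["PSE_POL3"]
                    + "C" * 18 + motifs.CANONICAL_ELEMENTS["TATA"]
                    + "C" * 24)
        genome, tss = self._genome(promoter)
        arch = motifs.annotate_promoter("L", genome, "chr1", tss, "+",
                                        upstream=len(promoter))
        els = {e.element: e for e in arch.entries}
        assert els["PSE"].occupied is None
        assert els["TATA"].occupied is None
        assert els["TATA"].start_rel == -30

    def test_missing_chromosome_raises(self):
        with pytest.raises(ValueError, match="missing sequence"):
            motifs.annotate_promoter("L", {}, "chrX", 100, "+")
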