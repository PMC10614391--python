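import io

import numpy as np
import pandas as pd
import pytest

from mgaseq import (
    HINDIII,
    MBOI,
    ContactMatrix,
    EnzymeSpec,
    Region,
    breakpoint_from_split,
    classify_translocation,
    cluster_breakpoints,
    expected_junction,
    parse_sam_splits,
    partition_junction_reads,
    screen_trans_blocks,
)
from mgaseq.genome import BinnedGenome
from mgaseq.simulate import (
    SimConfig,
    TranslocationSpec,
    random_translocations,
    simulate_cnv_segments,
    simulate_read_pairs_with_junction,
    simulate_split_reads,
)
from mgaseq.sv import (
    AlignedPart,
    BreakpointCandidate,
    BreakpointEnd,
    SplitAlignment,
    reverse_complement,
)


class TestJunctions:
    def test_hindiii_junction(self):
        assert expected_junction(HINDIII) == "AAGCTAGCTT"

    def test_mboi_junction(self):
        assert expected_junction(MBOI) == "GATCGATC"

    def test_blunt_cutter_rejoins_its_site(self):
        # mid-site blunt cut leaves nothing to fill in: halves rejoin to S
        alu = EnzymeSpec("AluI", "AGCT", 2)
        assert expected_junction(alu) == "AGCT"

    @pytest.mark.parametrize("enzyme", [HINDIII, MBOI])
    def test_junction_is_own_reverse_complement(self, enzyme):
        j = expected_junction(enzyme)
        assert j == reverse_complement(j)

    def test_non_palindromic_site_unsupported(self):
        with pytest.raises(ValueError, match="palindromic"):
            EnzymeSpec("BadI", "AAGCTA", 1)

    def test_three_prime_overhang_unsupported(self):
        with pytest.raises(ValueError, match="3'"):
            EnzymeSpec("WeirdI", "AAGCTT", 4)


class TestPartition:
    JUNCTION = "AAGCTAGCTT"

    def test_pair_with_junction_in_one_mate(self):
        pairs = [("r1", "TT" + self.JUNCTION + "GG", "ACGT" * 10)]
        w, wo, frac = partition_junction_reads(pairs, self.JUNCTION)
        assert w == ["r1"] and wo == [] and frac == 1.0

    def test_fraction_one_third(self):
        pairs = [
            ("r1", self.JUNCTION, "ACGTACGT"),
            ("r2", "ACGTACGT", "TTTTTTTT"),
            ("r3", "GGGGGGGG", "CCCCCCCC"),
        ]
        _, _, frac = partition_junction_reads(pairs, self.JUNCTION)
        assert frac == pytest.approx(1 / 3)

    def test_reverse_complement_strand_detected(self):
        j = "GATCAATC"  # non-palindromic on purpose
        pairs = [("r1", "TT" + reverse_complement(j) + "GG", "AAAA")]
        w, _, _ = partition_junction_reads(pairs, j)
        assert w == ["r1"]

    def test_planted_truth_recovered(self):
        cfg = SimConfig(seed=11, junction_fraction=0.15)
        pairs, truth = simulate_read_pairs_with_junction(cfg, 200)
        w, wo, frac = partition_junction_reads(pairs, self.JUNCTION)
        assert set(w) == truth
        assert len(w) == 30
        assert frac == pytest.approx(0.15)

    def test_empty_stream_reports_undefined_fraction(self):
        with pytest.warns(UserWarning, match="undefined"):
            _, _, frac = partition_junction_reads([], self.JUNCTION)
        assert frac is None


class TestBreakpointFromSplit:
    def test_forward_split(self):
        aln = SplitAlignment(
            "r",
            AlignedPart("chrA", 1000, "+", "60M40S"),
            AlignedPart("chrB", 5000, "+", "60S40M"),
        )
        c = breakpoint_from_split(aln)
        assert (c.end_a.chrom, c.end_a.pos, c.end_a.side) == ("chrA", 1059, "right")
        assert (c.end_b.chrom, c.end_b.pos, c.end_b.side) == ("chrB", 5000, "left")

    def test_mirrored_split(self):
        aln = SplitAlignment(
            "r",
            AlignedPart("chrA", 1000, "+", "40S60M"),
            AlignedPart("chrB", 5000, "+", "40M60S"),
        )
        c = breakpoint_from_split(aln)
        # read-upstream part is the chrB one (no leading clip)
        assert (c.end_a.chrom, c.end_a.pos) == ("chrA", 1000)
        assert (c.end_b.chrom, c.end_b.pos) == ("chrB", 5039)

    def test_strand_consistency_under_reverse_complement(self):
        fwd = SplitAlignment(
            "r",
            AlignedPart("chrA", 1000, "+", "60M40S"),
            AlignedPart("chrB", 5000, "+", "60S40M"),
        )
        rc = SplitAlignment(
            "r",
            AlignedPart("chrB", 5000, "-", "60S40M"),
            AlignedPart("chrA", 1000, "-", "60M40S"),
        )
        ca, cb = breakpoint_from_split(fwd), breakpoint_from_split(rc)
        assert (ca.end_a, ca.end_b) == (cb.end_a, cb.end_b)

    def test_micro_homology_left_aligned(self):
        # parts share 5 read bases; upstream keeps them
        aln = SplitAlignment(
            "r",
            AlignedPart("chrA", 1000, "+", "60M40S"),
            AlignedPart("chrB", 5000, "+", "55S45M"),
        )
        c = breakpoint_from_split(aln)
        assert c.end_a.pos == 1059
        assert c.end_b.pos == 5005  # shifted past the homologous bases

    def test_read_length_disagreement_rejected(self):
        aln = SplitAlignment(
            "r",
            AlignedPart("chrA", 1000, "+", "60M40S"),
            AlignedPart("chrB", 5000, "+", "40M"),
        )
        with pytest.raises(ValueError, match="read length"):
            breakpoint_from_split(aln)

    def test_same_side_clips_rejected(self):
        aln = SplitAlignment(
            "r",
            AlignedPart("chrA", 1000, "+", "100M"),
            AlignedPart("chrB", 5000, "+", "100M"),
        )
        with pytest.raises(ValueError, match="same side"):
            breakpoint_from_split(aln)


class TestSamParsing:
    def test_minimal_sam_with_sa_tag(self):
        sam = (
            "@SQ\tSN:chrA\tLN:100000\n"
            "r1\t0\tchrA\t1000\t60\t60M40S\t*\t0\t0\t"
            + "A" * 100
            + "\t*\tSA:Z:chrB,5000,+,60S40M,60,0;\n"
            "r2\t2048\tchrB\t5000\t60\t60S40M\t*\t0\t0\t"
            + "A" * 100
            + "\t*\tSA:Z:chrA,1000,+,60M40S,60,0;\n"
        )
        alns = list(parse_sam_splits(io.StringIO(sam)))
        assert len(alns) == 1  # supplementary record not double-counted
        assert alns[0].read_id == "r1"
        assert alns[0].supplementary.chrom == "chrB"

    def test_multiple_sa_entries_highest_mapq_used(self):
        sam = (
            "r1\t0\tchrA\t1000\t60\t60M40S\t*\t0\t0\t" + "A" * 100 + "\t*\t"
            "SA:Z:chrB,5000,+,60S40M,10,0;chrC,7000,+,60S40M,55,0;\n"
        )
        (aln,) = parse_sam_splits(io.StringIO(sam))
        assert aln.supplementary.chrom == "chrC"

    def test_records_without_sa_skipped(self):
        sam = "r1\t0\tchrA\t1000\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        assert list(parse_sam_splits(io.StringIO(sam))) == []


class TestClustering:
    @staticmethod
    def _cand(read_id, pos_a, pos_b):
        return BreakpointCandidate(
            read_id,
            BreakpointEnd("chr1", pos_a, "right"),
            BreakpointEnd("chr2", pos_b, "left"),
        )

    def test_identical_candidates_consolidate(self):
        cands = [self._cand(f"r{i}", 100, 500) for i in range(5)]
        (call,) = cluster_breakpoints(cands)
        assert call.support == 5
        assert (call.end_a.pos, call.end_b.pos) == (100, 500)

    def test_mode_position_with_smallest_tie_break(self):
        cands = [
            self._cand("r1", 100, 500),
            self._cand("r2", 101, 500),
            self._cand("r3", 100, 500),
        ]
        (call,) = cluster_breakpoints(cands, tolerance_bp=5)
        assert call.end_a.pos == 100

    def test_distant_junctions_stay_separate(self, rng):
        truth = [(100_000, 500_000), (150_000, 900_000)]
        cands = []
        i = 0
        for pa, pb in truth:
            for _ in range(25):
                # jitter within tolerance, mode at the exact position
                ja = int(rng.integers(-2, 3)) if i % 3 else 0
                cands.append(self._cand(f"r{i}", pa + ja, pb))
                i += 1
        calls = cluster_breakpoints(cands, tolerance_bp=5)
        assert len(calls) == 2
        assert sorted((c.end_a.pos, c.end_b.pos) for c in calls) == truth

    def test_support_counts_distinct_reads(self):
        cands = [self._cand("rX", 100, 500), self._cand("rX", 100, 500)]
        (call,) = cluster_breakpoints(cands)
        assert call.support == 1


class TestScreenTransBlocks:
    def test_planted_block_found(self, rng):
        g = BinnedGenome([("chr1", 5_000_000), ("chr2", 5_000_000)], 100_000)
        n = g.n_bins
        dense = np.zeros((n, n))
        b1, b2 = g.chrom_bins("chr1"), g.chrom_bins("chr2")
        dense[np.ix_(b1, b2)] = rng.poisson(1.0, (b1.size, b2.size))
        dense[np.ix_(b1[10:15], b2[20:25])] = 50
        iu = np.triu_indices(n)
        m = ContactMatrix.from_entries(g, iu[0], iu[1], dense[iu])
        blocks = screen_trans_blocks(m)
        assert len(blocks) == 1
        ra, rb, ncells = blocks[0]
        assert (ra.start, ra.end) == (1_000_000, 1_500_000)
        assert (rb.start, rb.end) == (2_000_000, 2_500_000)
        assert ncells == 25

    def test_uniform_matrix_gives_no_candidates(self):
        g = BinnedGenome([("chr1", 1_000_000), ("chr2", 1_000_000)], 100_000)
        n = g.n_bins
        iu = np.triu_indices(n)
        m = ContactMatrix.from_entries(g, iu[0], iu[1], np.full(iu[0].size, 3.0))
        assert screen_trans_blocks(m) == []

    def test_two_blocks_on_different_chrom_pairs(self, rng):
        g = BinnedGenome(
            [("chr1", 3_000_000), ("chr2", 3_000_000), ("chr3", 3_000_000)],
            100_000,
        )
        n = g.n_bins
        dense = np.zeros((n, n))
        for ca, cb in (("chr1", "chr2"), ("chr1", "chr3"), ("chr2", "chr3")):
            ba, bb = g.chrom_bins(ca), g.chrom_bins(cb)
            dense[np.ix_(ba, bb)] = rng.poisson(1.0, (ba.size, bb.size))
        dense[np.ix_(g.chrom_bins("chr1")[0:3], g.chrom_bins("chr2")[5:8])] = 60
        dense[np.ix_(g.chrom_bins("chr2")[10:13], g.chrom_bins("chr3")[2:5])] = 60
        iu = np.triu_indices(n)
        m = ContactMatrix.from_entries(g, iu[0], iu[1], dense[iu])
        blocks = screen_trans_blocks(m)
        pairs = {(ra.chrom, rb.chrom) for ra, rb, _ in blocks}
        assert pairs == {("chr1", "chr2"), ("chr2", "chr3")}


class TestClassifyTranslocation:
    @staticmethod
    def _flat_cnv(level_a=0.0, step_a=0.0, break_a=10_000_000):
        rows = []
        for chrom in ("chr1", "chr2"):
            for start in range(0, 20_000_000, 50_000):
                log2 = level_a
                if chrom == "chr1" and start >= break_a:
                    log2 += step_a
                rows.append(
                    {"chrom": chrom, "start": start, "end": start + 50_000,
                     "log2": log2}
                )
        return pd.DataFrame(rows)

    @staticmethod
    def _bp(pos_a=10_000_000, pos_b=8_000_000):
        from mgaseq.sv import BreakpointCall

        return BreakpointCall(
            BreakpointEnd("chr1", pos_a, "right"),
            BreakpointEnd("chr2", pos_b, "left"),
            support=20,
        )

    def test_flat_profile_is_balanced(self):
        call = classify_translocation(self._bp(), self._flat_cnv())
        assert call.type == "balanced"
        assert call.cnv_step_a == pytest.approx(0.0)

    def test_copy_loss_across_breakpoint_is_unbalanced(self):
        call = classify_translocation(
            self._bp(), self._flat_cnv(step_a=-1.0)
        )
        assert call.type == "unbalanced"
        assert call.cnv_step_a == pytest.approx(-1.0, abs=0.05)

    def test_noisy_planted_step_called_unbalanced(self, rng):
        hits = 0
        for trial in range(100):
            cnv = self._flat_cnv(step_a=0.8)
            cnv["log2"] += rng.normal(0, 0.1, len(cnv))
            call = classify_translocation(self._bp(), cnv)
            hits += call.type == "unbalanced"
        assert hits >= 99

    def test_breakpoint_near_chromosome_start_warns(self):
        with pytest.warns(UserWarning, match="flank reduced"):
            classify_translocation(self._bp(pos_a=100_000), self._flat_cnv())

    def test_uncovered_neighbourhood_rejected(self):
        cnv = self._flat_cnv()
        bad = self._bp().__class__(
            BreakpointEnd("chr9", 1_000_000, "right"),
            BreakpointEnd("chr2", 8_000_000, "left"),
            support=1,
        )
        with pytest.raises(ValueError, match="does not cover"):
            classify_translocation(bad, cnv)


class TestEndToEndRecovery:
    def test_planted_unbalanced_translocation_recovered_exactly(self):
        spec = TranslocationSpec("chr1", 5_000_000, "chr2", 7_000_000,
                                 split_support=20, cnv_step=1.0)
        cfg = SimConfig(seed=42, translocations=(spec,))
        sam_text, truth = simulate_split_reads(cfg)
        cands = [
            breakpoint_from_split(a)
            for a in parse_sam_splits(sam_text.splitlines())
        ]
        (call,) = cluster_breakpoints(cands)
        assert (call.end_a.chrom, call.end_a.pos) == ("chr1", 5_000_000)
        assert (call.end_b.chrom, call.end_b.pos) == ("chr2", 7_000_000)
        assert call.support == 20
        cnv = simulate_cnv_segments(cfg)
        typed = classify_translocation(call, cnv)
        assert typed.type == "unbalanced"
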