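import numpy as np
import pytest

from spacerscope.io_core import AnnotationSet, GeneFeature, RunConfig, revcomp, stage_rng
from spacerscope.protospacer_scan import (
    ProtospacerMatch,
    find_orfs,
    flank_self_check,
    orientation_vs_transcript,
    predict_interference,
    scan,
)


def brute_force_scan(spacer, genome, max_mm):
    """Oracle: Hamming distance at every window of both strands."""
    m = len(spacer)
    out = []
    for strand, query in (("+", spacer), ("-", revcomp(spacer))):
        for pos in range(len(genome) - m + 1):
            mm = sum(a != b for a, b in zip(genome[pos : pos + m], query))
            if mm <= max_mm:
                out.append((pos, strand, mm))
    return sorted(out)


class TestScan:
    def test_equals_brute_force_on_random_genomes(self):
        rng = stage_rng(31, "scan_oracle")
        bases = np.frombuffer(b"ACGT", dtype="S1")
        for trial in range(20):
            genome = rng.choice(bases, size=5000).tobytes().decode()
            pos = int(rng.integers(0, 5000 - 32))
            seq = list(genome[pos : pos + 32])
            for _ in range(int(rng.integers(0, 6))):
                j = int(rng.integers(32))
                seq[j] = "ACGT"[int(rng.integers(4))]
            spacer = "".join(seq) if rng.random() < 0.5 else revcomp("".join(seq))
            found = scan("sp", spacer, "g", genome, 5)
            got = sorted((m.start, m.strand, m.mismatches) for m in found)
            assert got == brute_force_scan(spacer, genome, 5)

    def test_planted_protospacers_recovered(self, host, escape_phage, config):
        _g, arrays, _t = host
        phage, truth = escape_phage
        for row in truth.itertuples():
            spacer = arrays[0].spacers[row.spacer_index]
            found = scan("sp", spacer, "ph", phage.sequence, config.max_mismatches, config)
            m = found[0]
            assert (m.start, m.end, m.strand) == (row.start, row.end, row.strand)
            assert m.mismatches == row.n_mismatches
            assert m.pam == row.pam
            assert m.seed_mismatch == row.seed_mismatch

    def test_seed_mismatch_flag_follows_positions(self, host, escape_phage, config):
        _g, arrays, _t = host
        phage, truth = escape_phage
        row = truth[truth.seed_mismatch].iloc[0]
        found = scan(
            "sp", arrays[0].spacers[row.spacer_index], "ph", phage.sequence, 5, config
        )
        m = found[0]
        lo, hi = config.seed_region
        assert any(lo <= p <= hi for p in m.mismatch_positions)
        assert m.mismatch_positions == [int(x) for x in row.mismatch_positions.split(",")]

    def test_edge_protospacer_pam_unavailable(self, config):
        rng = stage_rng(32, "edge")
        bases = np.frombuffer(b"ACGT", dtype="S1")
        genome = rng.choice(bases, size=200).tobytes().decode()
        spacer = genome[:32]  # protospacer at position 0: no 5' PAM bases
        m = [x for x in scan("sp", spacer, "g", genome, 0, config) if x.start == 0][0]
        assert m.pam is None
        assert m.pam_available is False
        assert m.pam_canonical is False

    def test_pam_convention_switch(self, config):
        rng = stage_rng(33, "pamside")
        bases = np.frombuffer(b"ACGT", dtype="S1")
        genome = rng.choice(bases, size=300).tobytes().decode()
        spacer = genome[100:132]
        cfg3 = RunConfig(pam_convention="three_prime_of_protospacer")
        m5 = scan("s", spacer, "g", genome, 0, config)[0]
        m3 = scan("s", spacer, "g", genome, 0, cfg3)[0]
        assert m5.pam == genome[98:100]
        assert m3.pam == genome[132:134]


class TestOrientation:
    ann = AnnotationSet("g", [GeneFeature("orf1", 100, 400, "+")])

    def mk(self, start, strand):
        return ProtospacerMatch("s", "g", start, start + 32, strand, 0)

    def test_minus_strand_match_in_plus_orf_is_complementary(self):
        assert (
            orientation_vs_transcript(self.mk(200, "-"), self.ann)
            == "antisense_crRNA_complementary"
        )

    def test_plus_strand_match_in_plus_orf_is_noncomplementary(self):
        assert (
            orientation_vs_transcript(self.mk(200, "+"), self.ann)
            == "sense_crRNA_noncomplementary"
        )

    def test_intergenic_match_has_no_transcript(self):
        assert orientation_vs_transcript(self.mk(500, "+"), self.ann) == "no_transcript"


class TestFlankSelfCheck:
    def test_repeat_flank_is_self(self, host, escape_phage, config):
        _g, arrays, _t = host
        phage, truth = escape_phage
        row = truth[truth.flank_mode == "repeat"].iloc[0]
        m = ProtospacerMatch("s", "ph", row.start, row.end, row.strand, 0)
        assert flank_self_check(m, phage.sequence, arrays[0].repeat, config) == "self"

    def test_random_flank_is_non_self(self, host, escape_phage, config):
        _g, arrays, _t = host
        phage, truth = escape_phage
        for row in truth[truth.flank_mode == "random"].itertuples():
            m = ProtospacerMatch("s", "ph", row.start, row.end, row.strand, 0)
            assert flank_self_check(m, phage.sequence, arrays[0].repeat, config) == "non_self"

    def test_seven_of_eight_identity_is_non_self_at_default(self, config):
        repeat = "A" * 20 + "GGATCGAT"
        genome = "T" * 50 + "GGATCGAA" + "C" * 32 + "T" * 50  # 7/8 match
        m = ProtospacerMatch("s", "g", 58, 90, "+", 0)
        assert flank_self_check(m, genome, repeat, config) == "non_self"
        genome2 = "T" * 50 + "GGATCGAT" + "C" * 32 + "T" * 50
        assert flank_self_check(m, genome2, repeat, config) == "self"

    def test_truncated_flank_is_non_self(self, config):
        genome = "C" * 40
        m = ProtospacerMatch("s", "g", 4, 36, "+", 0)
        assert flank_self_check(m, genome, "G" * 28, config) == "non_self"


class TestPredictInterference:
    def mk(self, pam_ok, seed_mm, orient, flank, mm=0):
        m = ProtospacerMatch("s", "g", 0, 32, "+", mm)
        m.pam_canonical = pam_ok
        m.seed_mismatch = seed_mm
        m.orientation = orient
        m.flank_class = flank
        return m

    def test_escape_pam_antisense_is_iiib_only(self, config):
        call = predict_interference(
            self.mk(False, False, "antisense_crRNA_complementary", "non_self", 1), config
        )
        assert (call.typeIF_competent, call.typeIIIB_competent) == (False, True)
        assert "pam_noncanonical" in call.reasons

    def test_canonical_pam_antisense_is_both(self, config):
        call = predict_interference(
            self.mk(True, False, "antisense_crRNA_complementary", "non_self"), config
        )
        assert (call.typeIF_competent, call.typeIIIB_competent) == (True, True)
        assert call.reasons == []

    def test_sense_with_seed_mismatch_is_neither(self, config):
        call = predict_interference(
            self.mk(True, True, "sense_crRNA_noncomplementary", "non_self", 3), config
        )
        assert (call.typeIF_competent, call.typeIIIB_competent) == (False, False)
        assert {"seed_mismatch", "sense_orientation"} <= set(call.reasons)

    def test_self_flank_blocks_iiib(self, config):
        call = predict_interference(
            self.mk(False, False, "antisense_crRNA_complementary", "self"), config
        )
        assert call.typeIIIB_competent is False
        assert "self_flank" in call.reasons

    def test_orientation_flip_asymmetry(self, config):
        """A IIIB-only target loses all competence when flipped to sense
        (transcription dependence); an IF-competent target keeps IF
        competence regardless of orientation."""
        iiib_only = self.mk(False, False, "antisense_crRNA_complementary", "non_self")
        flipped = self.mk(False, False, "sense_crRNA_noncomplementary", "non_self")
        a = predict_interference(iiib_only, config)
        b = predict_interference(flipped, config)
        assert a.typeIIIB_competent and not (b.typeIF_competent or b.typeIIIB_competent)

        if_target = self.mk(True, False, "sense_crRNA_noncomplementary", "non_self")
        if_flipped = self.mk(True, False, "antisense_crRNA_complementary", "non_self")
        assert predict_interference(if_target, config).typeIF_competent
        assert predict_interference(if_flipped, config).typeIF_competent


class TestFindOrfs:
    def test_simple_orf_found_on_both_strands(self):
        orf = "ATG" + "GCT" * 60 + "TAA"
        genome = "TTTT" + orf + "TTTT"
        ann = find_orfs(genome, min_len=150)
        plus = [g for g in ann.genes if g.strand == "+"]
        assert any(g.start == 4 and g.end == 4 + len(orf) for g in plus)
        ann_rc = find_orfs(revcomp(genome), min_len=150)
        assert any(g.strand == "-" for g in ann_rc.genes)
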