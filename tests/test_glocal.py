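"""Aligner correctness: worked examples, independent oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle_align as oracle
from spacerhost.glocal import (AlignmentInputError, AlignmentParams,
                               CalibrationError, SpacerMatch, SubjectGenome,
                               check_frame_preservation, glocal_align,
                               local_align, scan, score_alignment)
from spacerhost.sequtil import revcomp

from conftest import random_dna


class TestGlocalExamples:
    def test_exact_substring(self):
        a = glocal_align("ACGT", "AAACGTTT")
        assert a.score == 4
        assert (a.subject_start, a.subject_end) == (2, 6)
        assert a.identity == 1.0
        assert a.gaps_in_query == a.gaps_in_subject == 0

    def test_single_mismatch(self):
        # three matches and one mismatch is the best full-coverage alignment
        assert glocal_align("ACGT", "ACTT").score == 2

    def test_gap_beats_mismatches(self):
        # one length-2 subject insertion (cost 3) vs two mismatches (cost 4)
        a = glocal_align("ACGTACGT", "ACGTTTACGT")
        assert a.score == oracle.recursive_glocal_score("ACGTACGT", "ACGTTTACGT")
        assert a.score == 8 - 3
        assert a.gaps_in_query == 2

    def test_subject_shorter_than_query_rejected(self):
        with pytest.raises(AlignmentInputError):
            glocal_align("ACGTACGT", "ACGT")

    def test_ambiguous_base_scores_as_mismatch(self):
        assert glocal_align("AAAA", "TTAANATT").score == 2  # 3 matches - N


class TestOracleAgreement:
    def test_enumeration_validates_recursion(self):
        """The memoised recursion agrees with explicit alignment enumeration."""
        rng = np.random.default_rng(5)
        for _ in range(40):
            m = int(rng.integers(1, 5))
            n = int(rng.integers(m, 8))
            q, s = random_dna(rng, m), random_dna(rng, n)
            assert (oracle.recursive_glocal_score(q, s)
                    == oracle.enumerate_glocal_score(q, s)), (q, s)

    def test_dp_matches_recursion_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            m = int(rng.integers(1, 11))
            n = int(rng.integers(m, 15))
            q, s = random_dna(rng, m), random_dna(rng, n)
            assert glocal_align(q, s).score == oracle.recursive_glocal_score(q, s), (q, s)

    def test_local_matches_smith_waterman_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = int(rng.integers(2, 11))
            n = int(rng.integers(m, 15))
            q, s = random_dna(rng, m), random_dna(rng, n)
            a = local_align(q, s)
            expected = oracle.recursive_local_score(q, s)
            assert (a.score if a else 0) == expected, (q, s)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.data())
    def test_dp_matches_oracle_hypothesis(self, data):
        """Property form of the oracle check over generated sequence pairs."""
        dna = st.text(alphabet="ACGT", min_size=1, max_size=10)
        q = data.draw(dna)
        s = data.draw(st.text(alphabet="ACGT", min_size=len(q), max_size=14))
        assert glocal_align(q, s).score == oracle.recursive_glocal_score(q, s)

    def test_glocal_relaxes_global(self):
        """Free subject ends can only help relative to end-to-end alignment."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            m = int(rng.integers(2, 9))
            n = int(rng.integers(m, 12))
            q, s = random_dna(rng, m), random_dna(rng, n)
            assert (glocal_align(q, s).score
                    >= oracle.recursive_global_score(q, s)), (q, s)


class TestInvariants:
    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            m = int(rng.integers(4, 20))
            n = int(rng.integers(m, 60))
            q, s = random_dna(rng, m), random_dna(rng, n)
            assert (glocal_align(q, s).score
                    == glocal_align(revcomp(q), revcomp(s)).score)

    def test_traceback_rescores(self, params):
        rng = np.random.default_rng(10)
        for _ in range(150):
            m = int(rng.integers(4, 25))
            n = int(rng.integers(m, 80))
            a = glocal_align(random_dna(rng, m), random_dna(rng, n))
            assert score_alignment(a.aligned_query, a.aligned_subject, params) == a.score
            assert len(a.aligned_query.replace("-", "")) == m  # full coverage

    def test_local_never_below_glocal(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            m = int(rng.integers(4, 15))
            n = int(rng.integers(m, 40))
            q, s = random_dna(rng, m), random_dna(rng, n)
            loc = local_align(q, s)
            assert (loc.score if loc else 0) >= glocal_align(q, s).score

    def test_local_clips_noise_flanks(self):
        rng = np.random.default_rng(12)
        core = random_dna(rng, 10)
        # query carries the perfect core plus noise flanks absent from subject
        query = "AAAA" + core + "AAAA"
        subject = "GC" * 10 + core + "CG" * 10
        loc = local_align(query, subject)
        glo = glocal_align(query, subject)
        assert len(loc.aligned_query.replace("-", "")) <= len(query)
        assert len(glo.aligned_query.replace("-", "")) == len(query)
        assert loc.score >= glo.score

    def test_all_mismatch_has_no_local_alignment(self):
        assert local_align("AAAA", "TTTTTTTT") is None

    def test_substitutions_never_raise_score(self):
        rng = np.random.default_rng(13)
        spacer = random_dna(rng, 36)
        subject = random_dna(rng, 500) + spacer + random_dna(rng, 500)
        prev = glocal_align(spacer, subject).score
        mutated = list(spacer)
        order = rng.permutation(36)
        for k in range(0, 12):
            p = int(order[k])
            mutated[p] = "ACGT"[("ACGT".index(mutated[p]) + 1) % 4]
            score = glocal_align("".join(mutated), subject).score
            assert score <= prev
            prev = score


class TestFrameRule:
    @pytest.mark.parametrize("gq,gs,expected", [
        (1, 1, "ok"),      # compensated indel
        (0, 3, "ok"),      # frame-preserving triplet
        (3, 0, "ok"),
        (2, 0, "flagged"),
        (0, 1, "flagged"),
        (4, 1, "ok"),      # difference of three
    ])
    def test_gap_difference_rule(self, gq, gs, expected):
        m = SpacerMatch("sp1", "g", "+", 0, 36, 30, 1e-5, 0.9, gq, gs, "", "")
        assert check_frame_preservation(m) == expected


class TestScan:
    def test_planted_exact_protospacer_recovered(self, spacer_model, params):
        rng = np.random.default_rng(14)
        spacer = random_dna(rng, 36)
        genome = random_dna(rng, 1200) + spacer + random_dna(rng, 1264)
        ms = scan([("sp1", spacer)], [SubjectGenome("v", genome)], params,
                  spacer_model, 0.01)
        hit = [m for m in ms if m.identity == 1.0 and m.strand == "+"]
        assert len(hit) == 1
        assert (hit[0].start, hit[0].end) == (1200, 1236)
        assert hit[0].evalue <= 0.01

    def test_reverse_strand_coordinates(self, spacer_model, params):
        rng = np.random.default_rng(15)
        spacer = random_dna(rng, 36)
        genome = random_dna(rng, 800) + revcomp(spacer) + random_dna(rng, 1664)
        ms = scan([("sp1", spacer)], [SubjectGenome("v", genome)], params,
                  spacer_model, 0.01)
        hit = [m for m in ms if m.identity == 1.0]
        assert len(hit) == 1
        assert hit[0].strand == "-"
        assert (hit[0].start, hit[0].end) == (800, 836)

    def test_origin_spanning_hit_reported_once(self, spacer_model, params):
        rng = np.random.default_rng(16)
        spacer = random_dna(rng, 36)
        genome = random_dna(rng, 1200) + spacer + random_dna(rng, 1264)
        cut = 1200 + 18  # rotate so the plant straddles the origin
        rotated = genome[cut:] + genome[:cut]
        ms = scan([("sp1", spacer)], [SubjectGenome("v", rotated)], params,
                  spacer_model, 0.01)
        perfect = [m for m in ms if m.identity == 1.0]
        assert len(perfect) == 1
        m = perfect[0]
        assert m.start == len(genome) - 18 and m.end == m.start + 36

    def test_uncalibrated_length_raises(self, spacer_model, params):
        rng = np.random.default_rng(17)
        with pytest.raises(CalibrationError):
            scan([("sp1", random_dna(rng, 20))],
                 [SubjectGenome("v", random_dna(rng, 2500))],
                 params, spacer_model, 0.01)
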