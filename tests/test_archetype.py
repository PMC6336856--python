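"""Viral-sense orientation and archetype placement."""

import numpy as np
import pytest

from spacerhost.annotation import Feature
from spacerhost.archetype import (AmbiguousOrientationError, OrientationError,
                                  build_archetype, orient_genome,
                                  relative_position)
from spacerhost.glocal import SpacerMatch
from spacerhost.sequtil import revcomp

from conftest import random_dna


MOTIF_INSTANCE = "TAGTGTTAC"  # T->N, G->R: a valid NAGTRTTAC realisation


def clean_background(rng, n):
    """Random sequence free of chance origin-motif hits on either strand."""
    from spacerhost.sequtil import find_motif
    while True:
        s = random_dna(rng, n)
        if not find_motif(s, "NAGTRTTAC") and not find_motif(revcomp(s), "NAGTRTTAC"):
            return s


class TestOrientGenome:
    def test_forward_motif_not_flipped(self):
        rng = np.random.default_rng(1)
        seq = clean_background(rng, 500) + MOTIF_INSTANCE + clean_background(rng, 500)
        og = orient_genome("g", seq)
        assert not og.was_reverse_complemented
        assert og.seq == seq
        assert og.nonanucleotide_position == 500

    def test_reverse_motif_flips(self):
        rng = np.random.default_rng(2)
        seq = clean_background(rng, 500) + MOTIF_INSTANCE + clean_background(rng, 500)
        og = orient_genome("g", revcomp(seq))
        assert og.was_reverse_complemented
        assert og.seq == seq

    def test_iupac_semantics_reject_bad_r(self):
        rng = np.random.default_rng(3)
        seq = clean_background(rng, 200) + "AAGTCTTAC" + clean_background(rng, 200)
        with pytest.raises(OrientationError):
            orient_genome("g", seq)  # C fails R = A/G

    def test_motif_on_both_strands_is_ambiguous(self):
        rng = np.random.default_rng(4)
        seq = (clean_background(rng, 200) + MOTIF_INSTANCE
               + clean_background(rng, 100) + revcomp(MOTIF_INSTANCE)
               + clean_background(rng, 200))
        with pytest.raises(AmbiguousOrientationError):
            orient_genome("g", seq)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        seq = clean_background(rng, 300) + MOTIF_INSTANCE + clean_background(rng, 300)
        once = orient_genome("g", revcomp(seq))
        twice = orient_genome("g", once.seq, annotation=once.annotation)
        assert twice.seq == once.seq
        assert not twice.was_reverse_complemented

    def test_annotation_flips_with_sequence(self):
        rng = np.random.default_rng(6)
        genome = (clean_background(rng, 400) + revcomp(MOTIF_INSTANCE)
                  + clean_background(rng, 200))
        ann = [Feature("rep", 50, 350, "+", "gene")]  # input coordinates
        og = orient_genome("g", genome, annotation=ann)
        assert og.was_reverse_complemented
        f = og.annotation[0]
        n = len(genome)
        assert (f.start, f.end, f.strand) == (n - 350, n - 50, "-")
        assert og.seq[f.start:f.end] == revcomp(genome[50:350])


def _ann_2500():
    return [Feature("intergenic-A", 0, 200, "+", "intergenic"),
            Feature("cap", 200, 1370, "+", "gene"),
            Feature("intergenic-B", 1370, 1580, "+", "intergenic"),
            Feature("rep", 1580, 2480, "+", "gene")]


def mk_match(sp, genome, strand, start, end, mode="glocal"):
    return SpacerMatch(sp, genome, strand, start, end, 30, 1e-6, 1.0,
                       0, 0, "", "", mode=mode)


class TestRelativePosition:
    def test_midpoint_at_rep_start(self):
        m = mk_match("sp1", "g", "+", 1580, 1580)
        assert relative_position(m, _ann_2500(), 2500) == ("rep", 0.0)

    def test_two_thirds_through_rep(self):
        m = mk_match("sp1", "g", "+", 2162, 2198)  # midpoint 2180 = 1580 + 600
        seg, frac = relative_position(m, _ann_2500(), 2500)
        assert seg == "rep"
        assert frac == pytest.approx(2 / 3, abs=0.01)

    def test_intergenic_after_rep_wraps_through_origin(self):
        m = mk_match("sp1", "g", "+", 2490, 2510)  # midpoint at the origin gap
        seg, frac = relative_position(m, _ann_2500(), 2500)
        assert seg == "intergenic-A"
        assert 0 <= frac <= 1

    def test_rotation_invariance(self):
        # re-originating the circle moves annotation and match together
        ann = _ann_2500()
        shift = 15  # keeps every feature inside [0, 2500)
        rotated = [Feature(f.name, f.start + shift, f.end + shift,
                           f.strand, f.kind) for f in ann]
        m = mk_match("sp1", "g", "+", 2162, 2198)
        m_rot = mk_match("sp1", "g", "+", 2162 + shift, 2198 + shift)
        seg0, frac0 = relative_position(m, ann, 2500)
        seg1, frac1 = relative_position(m_rot, rotated, 2500)
        assert seg0 == seg1
        assert frac0 == pytest.approx(frac1, abs=1e-9)


class TestArchetype:
    def _oriented(self, rng, gid, rep_len=900):
        from spacerhost.archetype import OrientedGenome
        ann = [Feature("cap", 200, 1370, "+", "gene"),
               Feature("rep", 1580, 1580 + rep_len, "+", "gene")]
        seq = clean_background(rng, 2500 + rep_len - 900)
        return OrientedGenome(gid, seq, False, len(seq) - 9, ann)

    def test_segment_lengths_are_means(self):
        rng = np.random.default_rng(7)
        oriented = {"g1": self._oriented(rng, "g1", rep_len=900),
                    "g2": self._oriented(rng, "g2", rep_len=1100)}
        matches = [mk_match("sp1", "g1", "+", 1600, 1636),
                   mk_match("sp2", "g2", "+", 1600, 1636)]
        amap = build_archetype(matches, oriented)
        assert amap.segment_lengths["rep"] == pytest.approx(1000.0)
        assert sorted(amap.contributing_genomes) == ["g1", "g2"]

    def test_every_match_is_placed(self):
        rng = np.random.default_rng(8)
        oriented = {"g1": self._oriented(rng, "g1")}
        matches = [mk_match(f"sp{i}", "g1", "+", 100 * i, 100 * i + 36)
                   for i in range(1, 24)]
        amap = build_archetype(matches, oriented)
        assert len(amap.placements) == 23
        segs = {p.segment for p in amap.placements}
        assert segs <= {"cap", "rep", "intergenic-A", "intergenic-B"}

    def test_genome_without_annotation_excluded(self):
        rng = np.random.default_rng(9)
        from spacerhost.archetype import OrientedGenome
        og = OrientedGenome("bare", clean_background(rng, 2500), False, 2491, [])
        amap = build_archetype([mk_match("sp1", "bare", "+", 100, 136)],
                               {"bare": og})
        assert amap.placements == []

    def test_local_only_matches_marked(self):
        rng = np.random.default_rng(10)
        oriented = {"g1": self._oriented(rng, "g1")}
        matches = [mk_match("sp1", "g1", "+", 300, 336, mode="local")]
        amap = build_archetype(matches, oriented)
        assert amap.placements[0].local_only is True

    def test_archetype_coordinates_monotone_with_layout(self):
        rng = np.random.default_rng(11)
        oriented = {"g1": self._oriented(rng, "g1")}
        matches = [mk_match("sp1", "g1", "+", 210, 246),     # cap, early
                   mk_match("sp2", "g1", "+", 1600, 1636)]   # rep
        amap = build_archetype(matches, oriented)
        coords = [amap.archetype_coordinate(p) for p in amap.placements]
        assert coords[0] < coords[1]  # cap precedes rep in the layout
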