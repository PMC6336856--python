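"""Viral-sense orientation and the archetype genome map.

CRESS-DNA genomes are deposited in arbitrary orientation; the conserved
replication-origin nonanucleotide (NAGTRTTAC), which sits on the
encapsidated viral-sense strand, fixes a common orientation.  Because no
single genome carries every protospacer, targets are visualised on an
"archetype": a genome whose rep/cap/intergenic segment lengths are the
means over the contributing genomes, with each representative protospacer
placed at its fractional position within its segment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .annotation import Feature
from .glocal import SpacerMatch
from .sequtil import find_motif, revcomp

log = logging.getLogger(__name__)


class OrientationError(ValueError):
    """Origin motif absent from both strands."""


class AmbiguousOrientationError(ValueError):
    """Origin motif present on both strands."""


@dataclass
class OrientedGenome:
    """A circular genome put into viral-sense orientation."""

    id: str
    seq: str
    was_reverse_complemented: bool
    nonanucleotide_position: int
    annotation: list[Feature] = field(default_factory=list)

    def __len__(self):
        return len(self.seq)


def orient_genome(genome_id: str, seq: str, motif: str = "NAGTRTTAC",
                  annotation: list[Feature] | None = None) -> OrientedGenome:
    """Orient a circular genome so the origin motif reads forward.

    Raises :class:`OrientationError` when the motif is on neither strand
    and :class:`AmbiguousOrientationError` when it is on both.  Annotation
    coordinates are flipped along with the sequence.
    """
    fwd = find_motif(seq, motif, circular=True)
    rev = find_motif(revcomp(seq), motif, circular=True)
    if fwd and rev:
        raise AmbiguousOrientationError(
            f"{genome_id}: origin motif on both strands")
    if not fwd and not rev:
        raise OrientationError(f"{genome_id}: origin motif not found")
    annotation = list(annotation or [])
    if fwd:
        return OrientedGenome(genome_id, seq, False, fwd[0], annotation)
    n = len(seq)
    flipped = []
    for f in annotation:
        flipped.append(Feature(
            name=f.name, start=n - f.end, end=n - f.start,
            strand=("-" if f.strand == "+" else "+"), kind=f.kind,
            seqid=f.seqid))
    oriented = revcomp(seq)
    pos = find_motif(oriented, motif, circular=True)[0]
    genes_rev = [f for f in flipped if f.kind == "gene" and f.strand == "-"]
    if genes_rev:
        log.warning("%s: motif orientation conflicts with %d gene strand(s); "
                    "following the motif", genome_id, len(genes_rev))
    return OrientedGenome(genome_id, oriented, True, pos, flipped)


def _circular_segments(annotation: list[Feature], genome_len: int
                       ) -> list[tuple[str, int, int]]:
    """Ordered (name, start, end) covering the circle; end may exceed the
    genome length for the wrapping segment.  Gaps between annotated genes
    are labelled: the gap following rep (which contains the origin) is
    intergenic-A, the gap following cap is intergenic-B.
    """
    genes = sorted((f for f in annotation if f.kind == "gene"),
                   key=lambda f: f.start)
    if not genes:
        return [("unknown", 0, genome_len)]
    named = {f.name.lower(): f for f in genes}
    segs: list[tuple[str, int, int]] = []
    for i, f in enumerate(genes):
        segs.append((f.name, f.start, f.end))
        nxt = genes[(i + 1) % len(genes)]
        gap_start = f.end
        gap_end = nxt.start if nxt.start > f.end else nxt.start + genome_len
        if gap_end > gap_start:
            if "rep" in named and f.name == named["rep"].name:
                label = "intergenic-A"
            elif "cap" in named and f.name == named["cap"].name:
                label = "intergenic-B"
            else:
                label = f"intergenic-after-{f.name}"
            segs.append((label, gap_start, gap_end))
    return segs


def relative_position(match: SpacerMatch, annotation: list[Feature],
                      genome_len: int) -> tuple[str, float]:
    """(segment name, fractional position of the protospacer midpoint).

    Matches spanning a segment boundary are assigned to the segment
    containing their midpoint; positions are fractions of the segment
    length, 0 at the segment start.
    """
    mid = ((match.start + match.end) / 2) % genome_len
    for name, s, e in _circular_segments(annotation, genome_len):
        m = mid if mid >= s else mid + genome_len
        if s <= m < e:
            return name, (m - s) / (e - s)
    return "unknown", 0.0


@dataclass
class ArchetypePlacement:
    protospacer_id: str
    segment: str
    fraction: float
    strand: str
    source_genome: str
    local_only: bool = False


@dataclass
class ArchetypeMap:
    """Averaged genome with protospacers at relative coordinates."""

    segment_order: list[str]
    segment_lengths: dict[str, float]      # mean over contributing genomes
    placements: list[ArchetypePlacement]
    contributing_genomes: list[str]

    def archetype_coordinate(self, placement: ArchetypePlacement) -> float:
        """Absolute coordinate of a placement on the archetype layout."""
        pos = 0.0
        for name in self.segment_order:
            if name == placement.segment:
                return pos + placement.fraction * self.segment_lengths[name]
            pos += self.segment_lengths.get(name, 0.0)
        return pos

    def to_dict(self) -> dict:
        return {
            "segment_order": self.segment_order,
            "segment_lengths": self.segment_lengths,
            "contributing_genomes": self.contributing_genomes,
            "placements": [{
                "protospacer": p.protospacer_id, "segment": p.segment,
                "fraction": p.fraction, "strand": p.strand,
                "source_genome": p.source_genome, "local_only": p.local_only,
                "archetype_coordinate": self.archetype_coordinate(p),
            } for p in self.placements],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


#: Fig-style left-to-right layout of the archetype.
DEFAULT_SEGMENT_ORDER = ["intergenic-A", "cap", "intergenic-B", "rep"]


def build_archetype(matches: list[SpacerMatch],
                    oriented: dict[str, OrientedGenome],
                    segment_order: list[str] | None = None) -> ArchetypeMap:
    """Place representative matches on the averaged archetype genome.

    Genomes lacking rep or cap annotation are excluded with a warning (and
    their matches dropped); segment mean lengths are computed over the
    genomes that contribute at least one placement.
    """
    segment_order = segment_order or list(DEFAULT_SEGMENT_ORDER)
    usable: dict[str, list[tuple[str, int, int]]] = {}
    for gid, og in oriented.items():
        names = {f.name.lower() for f in og.annotation if f.kind == "gene"}
        if not {"rep", "cap"} <= names:
            log.warning("genome %s lacks rep/cap annotation; excluded", gid)
            continue
        usable[gid] = _circular_segments(og.annotation, len(og))

    placements = []
    contributing: list[str] = []
    for m in matches:
        if m.genome_id not in usable:
            continue
        og = oriented[m.genome_id]
        seg, frac = relative_position(m, og.annotation, len(og))
        placements.append(ArchetypePlacement(
            protospacer_id=f"p{m.spacer_id}", segment=seg, fraction=frac,
            strand=m.strand, source_genome=m.genome_id,
            local_only=(m.mode == "local")))
        if m.genome_id not in contributing:
            contributing.append(m.genome_id)

    seg_lengths: dict[str, float] = {}
    for name in segment_order:
        lens = []
        for gid in contributing:
            for sname, s, e in usable[gid]:
                if sname == name:
                    lens.append(e - s)
        if lens:
            seg_lengths[name] = sum(lens) / len(lens)
    return ArchetypeMap(segment_order=segment_order,
                        segment_lengths=seg_lengths,
                        placements=placements,
                        contributing_genomes=contributing)
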