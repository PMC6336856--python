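"""CRISPR repeat-array detection and leader calling.

Arrays of quasi-identical repeats are found by a k-mer seed-and-extend
strategy (CRT-like): exact 11-mers recurring at CRISPR-like periods seed
candidate arrays, repeat boundaries are extended while columns stay
conserved across instances, and degenerate terminal repeats — which often
do not share the seed — are recovered by a Hamming search one period
beyond each end of the array.

The leader side is called from the biology of spacer acquisition: new
spacers insert at the leader end, so the repeat farthest from the leader
is the oldest and typically degenerate.  The terminal repeat closest to
the consensus therefore marks the leader-proximal side; AT-richness of
the flank breaks ties.  Spacers are indexed sp1, sp2, ... walking away
from the leader, and their sequences are reported in transcription
(crRNA) sense.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .sequtil import at_fraction, revcomp


@dataclass
class Spacer:
    """One spacer, indexed by distance from the leader (sp1 = newest)."""

    index: int
    sequence: str      # transcription (crRNA) sense
    array_id: str = "array1"
    start: int = 0     # forward-strand coordinates, 0-based half-open
    end: int = 0

    @property
    def id(self) -> str:
        return f"sp{self.index}"


@dataclass
class CrisprArray:
    """An ordered repeat/spacer array on a contig.

    Coordinates are 0-based half-open and ascending on the forward strand.
    ``strand`` is the transcription orientation: "+" when the leader is on
    the left (transcription rightward).
    """

    contig_id: str
    array_id: str
    consensus: str                     # forward-strand reading
    instances: list[tuple[int, int]]
    spacer_seqs: list[str]             # forward-strand, left-to-right
    spacer_coords: list[tuple[int, int]]
    strand: str = "+"
    leader_side: str = "unknown"       # "left" | "right" | "unknown"
    leader_coords: tuple[int, int] | None = None
    spacers: list[Spacer] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.instances)

    @property
    def start(self) -> int:
        return self.instances[0][0]

    @property
    def end(self) -> int:
        return self.instances[-1][1]


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y) + abs(len(a) - len(b))


def _majority_consensus(strings: list[str]) -> str:
    out = []
    for col in zip(*strings):
        out.append(Counter(col).most_common(1)[0][0])
    return "".join(out)


def _agree_needed(r: int) -> int:
    return r if r <= 4 else max(4, -(-8 * r // 10))  # ceil(0.8 r)


def _extend_chain(g: str, seeds: list[int], k: int, max_repeat: int,
                  period_gap: int) -> tuple[int, int]:
    """Extend seed k-mer occurrences left/right while columns stay conserved.

    ``period_gap`` caps the extension so neighbouring instances never merge.
    Returns (left_extension, right_extension).
    """
    need = _agree_needed(len(seeds))
    min_diff = min(b - a for a, b in zip(seeds, seeds[1:])) if len(seeds) > 1 else period_gap
    room = min_diff - k  # repeat + spacer between seeds
    left = right = 0
    while k + left + right < max_repeat and left + right < room - 1:
        cols = [g[p - left - 1] for p in seeds if p - left - 1 >= 0]
        if len(cols) == len(seeds) and Counter(cols).most_common(1)[0][1] >= need:
            left += 1
            continue
        break
    while k + left + right < max_repeat and left + right < room - 1:
        cols = [g[p + k + right] for p in seeds if p + k + right < len(g)]
        if len(cols) == len(seeds) and Counter(cols).most_common(1)[0][1] >= need:
            right += 1
            continue
        break
    return left, right


def _grow_terminals(g: str, instances: list[tuple[int, int]], consensus: str,
                    spacer_len: tuple[int, int], tol: int) -> list[tuple[int, int]]:
    """Search one period beyond each array end for a degenerate repeat copy."""
    rl = len(consensus)
    grown = True
    instances = list(instances)
    while grown:
        grown = False
        e = instances[-1][1]
        best = None
        for s in range(e + spacer_len[0], e + spacer_len[1] + 1):
            if s + rl > len(g):
                break
            h = _hamming(g[s:s + rl], consensus)
            if h <= tol and (best is None or h < best[0]):
                best = (h, s)
        if best:
            instances.append((best[1], best[1] + rl))
            grown = True
        b = instances[0][0]
        best = None
        for gap in range(spacer_len[0], spacer_len[1] + 1):
            s = b - gap - rl
            if s < 0:
                continue
            h = _hamming(g[s:s + rl], consensus)
            if h <= tol and (best is None or h < best[0]):
                best = (h, s)
        if best:
            instances.insert(0, (best[1], best[1] + rl))
            grown = True
    return instances


def find_arrays(genome: str, min_repeats: int = 4,
                repeat_len: tuple[int, int] = (23, 47),
                spacer_len: tuple[int, int] = (20, 72),
                max_repeat_mismatch: int = 3, k: int = 11,
                terminal_extra_mismatch: int = 4,
                contig_id: str = "contig", flank_len: int = 150,
                call_leaders: bool = True) -> list[CrisprArray]:
    """Detect CRISPR arrays with at least *min_repeats* repeat instances.

    Returns an empty list when nothing qualifies.  Each array's leader is
    called (see :func:`call_leader`) unless ``call_leaders`` is False.
    """
    g = genome.upper()
    n = len(g)
    if n < k:
        return []
    period_min = repeat_len[0] + spacer_len[0]
    period_max = repeat_len[1] + spacer_len[1]
    terminal_tol = max_repeat_mismatch + terminal_extra_mismatch

    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        positions.setdefault(g[i:i + k], []).append(i)

    chains: list[list[int]] = []
    for pl in positions.values():
        if len(pl) < 2:
            continue
        run = [pl[0]]
        for p in pl[1:]:
            if period_min <= p - run[-1] <= period_max:
                run.append(p)
            else:
                if len(run) >= 2:
                    chains.append(run)
                run = [p]
        if len(run) >= 2:
            chains.append(run)
    # an array with r repeats yields a >= r-1 seed chain (the degenerate
    # terminal may be missing); require enough seeds for min_repeats
    chains = [c for c in chains if len(c) >= max(2, min_repeats - 1)]
    chains.sort(key=lambda c: (-len(c), c[0]))

    arrays: list[CrisprArray] = []
    claimed: list[tuple[int, int]] = []
    for chain in chains:
        span = (chain[0], chain[-1] + k)
        if any(span[0] < e and span[1] > s for s, e in claimed):
            continue
        left, right = _extend_chain(g, chain, k, repeat_len[1], period_min)
        rl = k + left + right
        if rl < repeat_len[0]:
            continue
        inst = [(p - left, p - left + rl) for p in chain]
        consensus = _majority_consensus([g[s:e] for s, e in inst])
        # drop non-conforming terminal instances, reject broken interiors
        while len(inst) > 2 and _hamming(g[inst[0][0]:inst[0][1]], consensus) > terminal_tol:
            inst = inst[1:]
        while len(inst) > 2 and _hamming(g[inst[-1][0]:inst[-1][1]], consensus) > terminal_tol:
            inst = inst[:-1]
        if any(_hamming(g[s:e], consensus) > max_repeat_mismatch for s, e in inst[1:-1]):
            continue
        inst = _grow_terminals(g, inst, consensus, spacer_len, terminal_tol)
        gaps = [b[0] - a[1] for a, b in zip(inst, inst[1:])]
        if any(not (spacer_len[0] <= gp <= spacer_len[1]) for gp in gaps):
            continue
        if len(inst) < min_repeats:
            continue
        spacer_coords = [(a[1], b[0]) for a, b in zip(inst, inst[1:])]
        arr = CrisprArray(
            contig_id=contig_id, array_id=f"array{len(arrays) + 1}",
            consensus=consensus, instances=inst,
            spacer_seqs=[g[s:e] for s, e in spacer_coords],
            spacer_coords=spacer_coords)
        claimed.append((inst[0][0], inst[-1][1]))
        arrays.append(arr)

    arrays.sort(key=lambda a: a.start)
    for i, a in enumerate(arrays):
        a.array_id = f"array{i + 1}"
        if call_leaders:
            call_leader(a, g, flank_len=flank_len)
    return arrays


def attach_satellite_arrays(arrays: list[CrisprArray], max_distance: int = 10_000,
                            min_repeats: int = 4) -> list[CrisprArray]:
    """Keep sub-minimum arrays only near a selected array with the same repeat.

    *arrays* should come from :func:`find_arrays` run with a lowered
    ``min_repeats`` so that candidate satellites are present.  A small array
    survives when it lies within *max_distance* of an array with at least
    *min_repeats* repeats and shares its repeat sequence on either strand.
    """
    selected = [a for a in arrays if a.n_repeats >= min_repeats]
    out = list(selected)
    for a in arrays:
        if a.n_repeats >= min_repeats:
            continue
        for big in selected:
            dist = max(big.start - a.end, a.start - big.end, 0)
            if dist <= max_distance and _repeat_similar(a.consensus, big.consensus):
                out.append(a)
                break
    out.sort(key=lambda a: a.start)
    return out


def _repeat_similar(c1: str, c2: str, tol: int = 2) -> bool:
    """Same repeat on either strand, tolerating boundary slop."""
    short, long_ = sorted((c1, c2), key=len)
    for cand in (long_, revcomp(long_)):
        for off in range(len(cand) - len(short) + 1):
            if _hamming(cand[off:off + len(short)], short) <= tol:
                return True
    return False


def call_leader(array: CrisprArray, genome: str, flank_len: int = 150,
                at_margin: float = 0.0) -> CrisprArray:
    """Call the leader side of an array and re-index its spacers.

    Primary criterion: the terminal repeat *distal* to the leader is the
    degenerate one, so the leader sits on the side whose terminal repeat is
    closest to consensus.  Tie-break: the leader flank is AT-rich relative
    to the genome background.  If both criteria are uninformative the side
    is "unknown" and indexing defaults to leftmost-first.
    """
    g = genome.upper()
    first = g[array.instances[0][0]:array.instances[0][1]]
    last = g[array.instances[-1][0]:array.instances[-1][1]]
    mm_left = _hamming(first, array.consensus)
    mm_right = _hamming(last, array.consensus)
    side = "unknown"
    if mm_right > mm_left + 1:
        side = "left"
    elif mm_left > mm_right + 1:
        side = "right"
    else:
        bg_at = at_fraction(g)
        lf = g[max(0, array.start - flank_len):array.start]
        rf = g[array.end:array.end + flank_len]
        at_l, at_r = at_fraction(lf), at_fraction(rf)
        if at_l > at_r and at_l > bg_at + at_margin:
            side = "left"
        elif at_r > at_l and at_r > bg_at + at_margin:
            side = "right"

    array.leader_side = side
    array.strand = "-" if side == "right" else "+"
    if side == "right":
        array.leader_coords = (array.end, array.end + flank_len)
        ordered = list(zip(array.spacer_seqs, array.spacer_coords))[::-1]
        array.spacers = [Spacer(index=i + 1, sequence=revcomp(s),
                                array_id=array.array_id, start=c[0], end=c[1])
                         for i, (s, c) in enumerate(ordered)]
    else:
        array.leader_coords = (max(0, array.start - flank_len), array.start)
        array.spacers = [Spacer(index=i + 1, sequence=s, array_id=array.array_id,
                                start=c[0], end=c[1])
                         for i, (s, c) in enumerate(zip(array.spacer_seqs,
                                                        array.spacer_coords))]
    return array


def pooled_spacers(arrays: list[CrisprArray]) -> list[Spacer]:
    """Spacers from all arrays, array-qualified ids preserved via array_id."""
    out = []
    for a in arrays:
        out.extend(a.spacers)
    return out


def arrays_to_gff(arrays: list[CrisprArray]):
    from .annotation import Feature
    feats = []
    for a in arrays:
        feats.append(Feature(a.array_id, a.start, a.end, a.strand,
                             "repeat_region", a.contig_id))
        if a.leader_coords:
            feats.append(Feature(f"{a.array_id}-leader", a.leader_coords[0],
                                 a.leader_coords[1], a.strand, "leader",
                                 a.contig_id))
        for sp in a.spacers:
            feats.append(Feature(f"{a.array_id}-sp{sp.index}", sp.start, sp.end,
                                 a.strand, "spacer", a.contig_id))
    return feats
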