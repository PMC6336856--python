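"""PAM discovery from protospacer-flanking sequences.

Flanks are read on the non-target strand (the strand matching the spacer,
i.e. the crRNA sense); "upstream" means 5' of that reading, which for
Type I systems is where the PAM sits.  Each selected match contributes
one 10-nt flank; stacking them gives a position frequency matrix whose
per-column information content (2 − H bits) is the sequence-logo letter
height.  A motif call reports the positions whose dominant base clears a
conservation threshold (CCN-style), plus how many flanks carry the
complete motif.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glocal import SpacerMatch, best_match_per_spacer
from .sequtil import revcomp

log = logging.getLogger(__name__)

_ALPHABET = "ACGT"


@dataclass
class FlankSet:
    """Aligned flanking sequences of selected protospacers."""

    side: str                 # "upstream" | "downstream"
    flank_len: int
    sequences: list[str]      # non-target-strand reading, all same length
    selection: str            # "identical-only" | "best-per-spacer" | "all"
    match_ids: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.sequences)


@dataclass
class PositionFrequencyMatrix:
    """Per-position base frequencies and information content.

    Positions are -flank_len..-1 for upstream flanks and +1..+flank_len for
    downstream flanks.  Information content is 2 − H bits per column,
    optionally with the small-sample correction e(n) = 3 / (2 ln2 · n).
    """

    positions: list[int]
    freqs: pd.DataFrame            # index positions, columns A C G T
    counts: pd.DataFrame
    n_sequences: int
    information: pd.Series         # bits per position
    small_sample_corrected: bool = False


@dataclass
class MotifCall:
    """IUPAC-style motif over the conserved positions of a flank PFM."""

    motif: str                     # e.g. "CCN"
    offsets: list[int]             # positions of motif characters
    per_position_conservation: dict[int, float]
    completeness: float            # flanks carrying the full motif
    any_position: float            # flanks carrying at least one motif base


def extract_flanks(matches: list[SpacerMatch], genomes, side: str = "upstream",
                   flank_len: int = 10, selection: str = "best-per-spacer",
                   genome_order: list[str] | None = None) -> FlankSet:
    """Extract protospacer flanks on the non-target strand.

    ``genomes`` maps genome id to a sequence string or a
    ``(sequence, circular)`` pair (sequences default to circular).  Matches
    on linear subjects without enough margin are skipped with a warning.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    if selection == "identical-only":
        chosen = [m for m in matches if m.identity == 1.0]
    elif selection == "best-per-spacer":
        chosen = best_match_per_spacer(matches, genome_order)
    elif selection == "all":
        chosen = list(matches)
    else:
        raise ValueError(f"unknown selection rule {selection!r}")

    seqs, ids = [], []
    for m in chosen:
        entry = genomes[m.genome_id]
        if isinstance(entry, str):
            seq, circular = entry, True
        else:
            seq, circular = entry[0], entry[1]
        n = len(seq)
        # upstream in spacer sense: before the 5' end of the crRNA-matching
        # reading. On the "+" strand that is left of start; on "-" it is
        # right of end, read back on the reverse complement.
        if (side == "upstream") == (m.strand == "+"):
            lo, hi = m.start - flank_len, m.start
        else:
            lo, hi = m.end, m.end + flank_len
        if circular:
            flank = "".join(seq[i % n] for i in range(lo, hi))
        else:
            if lo < 0 or hi > n:
                log.warning("match %s on %s lacks %s flank margin; skipped",
                            m.spacer_id, m.genome_id, side)
                continue
            flank = seq[lo:hi]
        if m.strand == "-":
            flank = revcomp(flank)
        seqs.append(flank.upper())
        ids.append(f"{m.spacer_id}:{m.genome_id}")
    return FlankSet(side=side, flank_len=flank_len, sequences=seqs,
                    selection=selection, match_ids=ids)


def build_pfm(flanks: FlankSet, small_sample_correction: bool = False
              ) -> PositionFrequencyMatrix:
    """Position frequency matrix + information content from a flank stack."""
    if len(flanks) < 2:
        raise ValueError("need at least two flank sequences")
    if flanks.side == "upstream":
        positions = list(range(-flanks.flank_len, 0))
    else:
        positions = list(range(1, flanks.flank_len + 1))
    counts = pd.DataFrame(0, index=positions, columns=list(_ALPHABET))
    for s in flanks.sequences:
        for pos, base in zip(positions, s):
            if base in _ALPHABET:
                counts.loc[pos, base] += 1
    col_n = counts.sum(axis=1)
    freqs = counts.div(col_n.replace(0, np.nan), axis=0).fillna(0.0)
    ic = []
    for pos in positions:
        f = freqs.loc[pos].to_numpy()
        nz = f[f > 0]
        h = -(nz * np.log2(nz)).sum() if nz.size else 2.0
        val = 2.0 - h
        if small_sample_correction and col_n[pos] > 0:
            val -= 3.0 / (2.0 * math.log(2) * col_n[pos])
        ic.append(max(val, 0.0))
    return PositionFrequencyMatrix(
        positions=positions, freqs=freqs, counts=counts,
        n_sequences=len(flanks), information=pd.Series(ic, index=positions),
        small_sample_corrected=small_sample_correction)


def call_motif(pfm: PositionFrequencyMatrix, flanks: FlankSet,
               conservation_threshold: float = 0.6) -> MotifCall:
    """Call conserved positions into a motif string.

    Positions whose dominant base frequency reaches the threshold get that
    base; sub-threshold positions *between* called ones become N.  The
    completeness fraction counts flanks matching every called base, the
    any-position fraction those matching at least one.
    """
    called: dict[int, str] = {}
    conservation: dict[int, float] = {}
    for pos in pfm.positions:
        f = pfm.freqs.loc[pos]
        base = f.idxmax()
        if f[base] >= conservation_threshold:
            called[pos] = base
            conservation[pos] = float(f[base])
    if not called:
        return MotifCall(motif="", offsets=[], per_position_conservation={},
                         completeness=0.0, any_position=0.0)
    lo, hi = min(called), max(called)
    offsets = [p for p in pfm.positions if lo <= p <= hi]
    motif = "".join(called.get(p, "N") for p in offsets)

    pos_index = {p: i for i, p in enumerate(pfm.positions)}
    full = partial = 0
    for s in flanks.sequences:
        hits = sum(1 for p, b in called.items() if s[pos_index[p]] == b)
        full += hits == len(called)
        partial += hits >= 1
    n = len(flanks)
    return MotifCall(motif=motif, offsets=offsets,
                     per_position_conservation=conservation,
                     completeness=full / n if n else 0.0,
                     any_position=partial / n if n else 0.0)


def render_logo(pfm: PositionFrequencyMatrix, path) -> None:
    """Optional sequence-logo-style rendering (stacked IC-scaled bars)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2e7d32", "C": "#1565c0", "G": "#f9a825", "T": "#c62828"}
    fig, ax = plt.subplots(figsize=(max(4, len(pfm.positions) * 0.5), 2.5))
    for i, pos in enumerate(pfm.positions):
        bottom = 0.0
        order = pfm.freqs.loc[pos].sort_values().items()
        for base, f in order:
            h = f * pfm.information[pos]
            if h <= 0:
                continue
            ax.bar(i, h, bottom=bottom, color=colors[base], width=0.8)
            if h > 0.15:
                ax.text(i, bottom + h / 2, base, ha="center", va="center",
                        fontsize=8, color="white")
            bottom += h
    ax.set_xticks(range(len(pfm.positions)))
    ax.set_xticklabels(pfm.positions)
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pfm_to_tsv(pfm: PositionFrequencyMatrix, path) -> None:
    out = pfm.freqs.copy()
    out["information_bits"] = pfm.information
    out.index.name = "position"
    out.to_csv(path, sep="\t")


def flanks_to_fasta(flanks: FlankSet, path) -> None:
    with open(path, "w") as fh:
        for mid, s in zip(flanks.match_ids, flanks.sequences):
            fh.write(f">{mid}\n{s}\n")
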