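"""Small shared helpers for DNA handling.

Sequences are plain upper-case strings at the API surface; the aligner
works on uint8-encoded numpy arrays internally (A,C,G,T -> 0..3, anything
else -> 4, which scores as a mismatch against every base).
"""

from __future__ import annotations

import re

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: IUPAC nucleotide codes and the bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("A") + s.count("T")) / len(s)


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif (e.g. ``NAGTRTTAC``) into a regex."""
    parts = []
    for base in motif.upper():
        try:
            opts = IUPAC[base]
        except KeyError:
            raise ValueError(f"not an IUPAC nucleotide code: {base!r}") from None
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def iupac_matches(base: str, code: str) -> bool:
    """True when *base* is one of the bases the IUPAC *code* stands for."""
    return base.upper() in IUPAC.get(code.upper(), "")


def find_motif(seq: str, motif: str, circular: bool = False) -> list[int]:
    """Start positions of an IUPAC motif on the forward strand.

    For circular sequences the search wraps across the origin; positions are
    reported modulo ``len(seq)`` and deduplicated.
    """
    pat = iupac_regex(motif)
    search_in = seq + (seq[: len(motif) - 1] if circular and len(seq) >= len(motif) else "")
    hits = []
    for m in pat.finditer(search_in.upper()):
        pos = m.start() % len(seq) if seq else m.start()
        if pos not in hits:
            hits.append(pos)
    return hits
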