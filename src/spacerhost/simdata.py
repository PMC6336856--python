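"""Seeded generators for synthetic hosts and smacovirus-like genomes.

The host generator plants a subtype I-B-style CRISPR locus in a random
background: an AT-rich leader, ``n_spacers + 1`` copies of a 31-nt repeat
interleaved with unique random spacers, and a degenerate (3–6
substitutions) repeat at the end farthest from the leader — the signature
used to call the leader side.  Optionally a small satellite array with the
same repeat on the opposite strand is planted a few kb away, mirroring the
B1/B2 arrangement of *Ca.* Methanomassiliicoccus intestinalis.

The virus generator emits circular ~2.5-kb genomes with *rep* and *cap*
ORFs, a replication-origin nonanucleotide (``NAGTRTTAC``) shortly
downstream of the *rep* stop codon on the viral-sense strand, and planted
protospacers with controlled identity, gap counts, strand and an optional
``CCN`` PAM upstream in spacer-transcription sense.  Every plant is
recorded as ground truth.  Position 0 is the base following the
nonanucleotide, so the motif sits at the very end of the sequence.

Background composition is i.i.d. uniform A/C/G/T; all randomness flows
from ``SimConfig.seed`` (same seed, byte-identical output).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .annotation import Feature
from .sequtil import IUPAC, find_motif, revcomp

#: The B1 array repeat of Ca. M. intestinalis (31 nt).
DEFAULT_REPEAT = "GTTAGAAATCCATCTAAACTAGAATGTAAAT"
#: Conserved CRESS-DNA replication-origin nonanucleotide (IUPAC).
DEFAULT_NONANUCLEOTIDE = "NAGTRTTAC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


class SizingError(ValueError):
    """Configuration asks for more sequence than fits."""


class PlacementError(ValueError):
    """Planted elements cannot be placed without overlap."""


@dataclass
class PlantSpec:
    """Request for one planted protospacer."""

    spacer_index: int                 # 1-based from the leader
    target_strand: str = "viral"      # "viral" | "complementary"
    identity_fraction: float = 1.0
    n_gaps_query: int = 0             # extra bases in the protospacer
    n_gaps_subject: int = 0           # bases missing from the protospacer
    region: str = "rep"               # "rep" | "cap" | "intergenic"
    with_pam: bool = True

    def __post_init__(self):
        if not (0 < self.identity_fraction <= 1):
            raise ValueError("identity_fraction must be in (0, 1]")
        if self.target_strand not in ("viral", "complementary"):
            raise ValueError(f"bad target_strand {self.target_strand!r}")
        if self.region not in ("rep", "cap", "intergenic"):
            raise ValueError(f"bad region {self.region!r}")


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic data.

    Defaults follow the system being emulated: a ~2.5 Mb host with a
    112-repeat array of the 31-nt repeat, 35–37-nt spacers, ~2.5 kb
    circular viruses with *rep* and *cap*, the NAGTRTTAC origin
    nonanucleotide and a CCN PAM.
    """

    seed: int = 0
    host_length: int = 2_500_000
    repeat_seq: str = DEFAULT_REPEAT
    n_spacers: int = 111
    spacer_len_range: tuple[int, int] = (35, 37)
    leader_len: int = 150
    leader_at_fraction: float = 0.7
    leader_side: str = "left"
    satellite_repeats: int = 3        # 0 disables the satellite array
    satellite_distance: int = 3000
    virus_length: int = 2500
    rep_len: int = 900                # must be a multiple of 3
    cap_len: int = 1170               # ~30% larger than rep
    rep_nona_gap: int = 15            # "shortly downstream of the rep stop"
    nonanucleotide: str = DEFAULT_NONANUCLEOTIDE
    pam: str = "CCN"
    planted: list[PlantSpec] = field(default_factory=list)

    def __post_init__(self):
        if len(self.nonanucleotide) != 9:
            raise ValueError("nonanucleotide must be 9 nt")
        if self.rep_len % 3 or self.cap_len % 3:
            raise ValueError("gene lengths must be multiples of 3")
        core = self.rep_len + self.cap_len + self.rep_nona_gap + 9
        if self.virus_length - core < 20:
            raise SizingError("virus_length leaves no room for intergenic regions")
        if self.leader_side not in ("left", "right"):
            raise ValueError("leader_side must be 'left' or 'right'")
        if not (0 <= self.leader_at_fraction <= 1):
            raise ValueError("leader_at_fraction must be in [0, 1]")


@dataclass
class ArrayTruth:
    """Ground truth for one planted CRISPR locus, in forward coordinates."""

    start: int
    end: int
    strand: str                     # "+" leader left, "-" leader right
    leader_side: str
    leader_start: int
    leader_end: int
    repeat_instances: list[tuple[int, int]]
    spacers: list[str]              # transcription sense, sp1 first
    spacer_coords: list[tuple[int, int]]
    degenerate_repeat: tuple[int, int]


@dataclass
class HostTruth:
    contig_id: str
    length: int
    main: ArrayTruth
    satellite: ArrayTruth | None = None


@dataclass
class ProtospacerTruth:
    """Realised properties of one planted protospacer."""

    spacer_index: int
    virus_id: str
    start: int
    end: int
    strand: str       # "+" viral-sense, "-" complementary
    identity: float
    gaps_in_query: int
    gaps_in_subject: int
    region: str
    with_pam: bool
    pam: str


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _rand_at_seq(rng: np.random.Generator, n: int, at: float) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def _degenerate(rng: np.random.Generator, repeat: str) -> str:
    n_sub = int(rng.integers(3, 7))
    pos = rng.choice(len(repeat), size=n_sub, replace=False)
    out = list(repeat)
    for p in pos:
        out[p] = "ACGT"[(("ACGT".index(out[p])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _realise_iupac(rng: np.random.Generator, motif: str) -> str:
    return "".join(IUPAC[b][int(rng.integers(0, len(IUPAC[b])))] for b in motif.upper())


# ---------------------------------------------------------------------------
# host
# ---------------------------------------------------------------------------

def _build_array_block(rng, config: SimConfig, n_spacers: int
                       ) -> tuple[str, dict]:
    """Leader-left array block and its within-block coordinates."""
    lo, hi = config.spacer_len_range
    spacers: list[str] = []
    seen = set()
    while len(spacers) < n_spacers:
        s = _rand_seq(rng, int(rng.integers(lo, hi + 1)))
        if s not in seen and config.repeat_seq not in s:
            seen.add(s)
            spacers.append(s)
    leader = _rand_at_seq(rng, config.leader_len, config.leader_at_fraction)
    parts = [leader]
    rep_coords, sp_coords = [], []
    pos = len(leader)
    for s in spacers:
        parts.append(config.repeat_seq)
        rep_coords.append((pos, pos + len(config.repeat_seq)))
        pos += len(config.repeat_seq)
        parts.append(s)
        sp_coords.append((pos, pos + len(s)))
        pos += len(s)
    deg = _degenerate(rng, config.repeat_seq)
    parts.append(deg)
    rep_coords.append((pos, pos + len(deg)))
    pos += len(deg)
    block = "".join(parts)
    return block, {"leader": (0, len(leader)), "repeats": rep_coords,
                   "spacers": spacers, "spacer_coords": sp_coords,
                   "degenerate": rep_coords[-1]}


def _place_block(block: str, meta: dict, offset: int, flipped: bool
                 ) -> ArrayTruth:
    B = len(block)

    def fwd(c):
        s, e = c
        return (offset + B - e, offset + B - s) if flipped else (offset + s, offset + e)

    leader = fwd(meta["leader"])
    side = "right" if flipped else "left"
    return ArrayTruth(
        start=offset, end=offset + B,
        strand="-" if flipped else "+",
        leader_side=side,
        leader_start=leader[0], leader_end=leader[1],
        repeat_instances=sorted(fwd(c) for c in meta["repeats"]),
        spacers=list(meta["spacers"]),
        spacer_coords=[fwd(c) for c in meta["spacer_coords"]],
        degenerate_repeat=fwd(meta["degenerate"]))


def generate_host(config: SimConfig, contig_id: str = "host") -> tuple[str, HostTruth]:
    """Synthetic host contig with a planted CRISPR locus (plus satellite).

    Returns the sequence and the ground truth.  Raises :class:`SizingError`
    when the array footprint does not fit in ``host_length``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    main_block, main_meta = _build_array_block(rng, config, config.n_spacers)
    sat_block = sat_meta = None
    if config.satellite_repeats >= 2:
        sat_block, sat_meta = _build_array_block(rng, config,
                                                 config.satellite_repeats - 1)
    footprint = len(main_block) + (
        (config.satellite_distance + len(sat_block)) if sat_block else 0)
    margin = 100
    if footprint + 2 * margin > config.host_length:
        raise SizingError(
            f"array footprint {footprint} nt does not fit in host_length "
            f"{config.host_length}")
    bg = _rand_seq(rng, config.host_length)
    lo, hi = margin, config.host_length - footprint - margin
    offset = int(rng.integers(lo, hi + 1))

    main_flipped = config.leader_side == "right"
    pieces = [bg[:offset],
              revcomp(main_block) if main_flipped else main_block]
    main_truth = _place_block(main_block, main_meta, offset, main_flipped)
    pos = offset + len(main_block)
    sat_truth = None
    if sat_block:
        sat_off = pos + config.satellite_distance
        pieces.append(bg[pos:sat_off])
        # satellite on the opposite strand of the main array
        sat_flipped = not main_flipped
        pieces.append(revcomp(sat_block) if sat_flipped else sat_block)
        sat_truth = _place_block(sat_block, sat_meta, sat_off, sat_flipped)
        pos = sat_off + len(sat_block)
    pieces.append(bg[pos:])
    seq = "".join(pieces)
    assert len(seq) == config.host_length
    return seq, HostTruth(contig_id=contig_id, length=len(seq),
                          main=main_truth, satellite=sat_truth)


# ---------------------------------------------------------------------------
# virus
# ---------------------------------------------------------------------------

def _build_orf(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + TAA, of the requested length."""
    n_codons = length // 3 - 2
    codons = []
    while len(codons) < n_codons:
        c = _rand_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _mutate_protospacer(rng, spacer: str, spec: PlantSpec
                        ) -> tuple[str, float, int, int]:
    """Derive the protospacer from the spacer with the requested edits.

    Gap runs are contiguous (a single run per side) and kept away from the
    protospacer ends so recovery is anchored; substitutions land on aligned
    (non-inserted) interior positions.  Returns (sequence, realised
    identity, gaps_in_query, gaps_in_subject).
    """
    L = len(spacer)
    gq, gs = spec.n_gaps_query, spec.n_gaps_subject
    if gq + gs + 8 > L:
        raise PlacementError("too many gaps for the spacer length")
    seq = list(spacer)
    aligned = [True] * L  # per protospacer base: aligned to a spacer base?
    if gs:  # deletion: protospacer misses gs spacer bases
        u = int(rng.integers(2, L // 2 - gs)) if L // 2 - gs > 2 else 2
        del seq[u:u + gs]
        del aligned[u:u + gs]
    if gq:  # insertion: protospacer carries gq extra bases
        v = int(rng.integers(len(seq) // 2, len(seq) - 2))
        ins = _rand_seq(rng, gq)
        seq[v:v] = list(ins)
        aligned[v:v] = [False] * gq
    columns = L + gq
    matched = L - gs
    n_sub = round(columns * (1 - spec.identity_fraction)) - gq - gs
    if n_sub < 0:
        n_sub = 0
    candidates = [i for i in range(2, len(seq) - 2) if aligned[i]]
    if n_sub > len(candidates):
        raise PlacementError("cannot realise requested identity")
    for i in rng.choice(len(candidates), size=n_sub, replace=False):
        p = candidates[int(i)]
        seq[p] = "ACGT"[("ACGT".index(seq[p]) + int(rng.integers(1, 4))) % 4]
    identity = (matched - n_sub) / columns
    return "".join(seq), identity, gq, gs


def generate_virus(config: SimConfig, truth_spacers: list[str],
                   virus_id: str = "virus1", planted: list[PlantSpec] | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[str, list[Feature], list[ProtospacerTruth]]:
    """Circular virus genome with planted protospacers and ground truth.

    ``truth_spacers`` are spacer sequences in transcription sense, sp1
    first (e.g. ``HostTruth.main.spacers``).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    planted = config.planted if planted is None else planted
    for p in planted:
        if not (1 <= p.spacer_index <= len(truth_spacers)):
            raise PlacementError(f"spacer index {p.spacer_index} not available")

    L = config.virus_length
    inter_total = L - config.rep_len - config.cap_len - config.rep_nona_gap - 9
    a = inter_total // 2
    b = inter_total - a
    cap_start = a
    cap_end = a + config.cap_len
    rep_start = cap_end + b
    rep_end = rep_start + config.rep_len
    nona_start = L - 9

    seq = (_rand_seq(rng, a) + _build_orf(rng, config.cap_len)
           + _rand_seq(rng, b) + _build_orf(rng, config.rep_len)
           + _rand_seq(rng, config.rep_nona_gap)
           + _realise_iupac(rng, config.nonanucleotide))
    assert len(seq) == L

    features = [
        Feature("intergenic-A", 0, cap_start, "+", "intergenic", virus_id),
        Feature("cap", cap_start, cap_end, "+", "gene", virus_id),
        Feature("intergenic-B", cap_end, rep_start, "+", "intergenic", virus_id),
        Feature("rep", rep_start, rep_end, "+", "gene", virus_id),
        Feature("origin-nonanucleotide", nona_start, L, "+", "origin", virus_id),
    ]
    regions = {"rep": [(rep_start + 3, rep_end - 3)],
               "cap": [(cap_start + 3, cap_end - 3)],
               "intergenic": [(0, cap_start), (cap_end, rep_start)]}

    claimed: list[tuple[int, int]] = [(nona_start - 1, L)]
    plants = []  # (start, replaced_len, chunk, truth-in-progress)
    for spec in planted:
        spacer = truth_spacers[spec.spacer_index - 1]
        proto, identity, gq, gs = _mutate_protospacer(rng, spacer, spec)
        pam_inst = _realise_iupac(rng, config.pam) if spec.with_pam else ""
        win = len(spacer)  # window of genome replaced by the protospacer
        placed = False
        for _ in range(200):
            ranges = regions[spec.region]
            rs, re_ = ranges[int(rng.integers(0, len(ranges)))]
            lo = rs + (3 if spec.with_pam and spec.target_strand == "viral" else 0)
            hi = re_ - win - (3 if spec.with_pam and spec.target_strand == "complementary" else 0)
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            pad = 12
            if any(start - pad < e and start + win + pad > s for s, e in claimed):
                continue
            claimed.append((start - 3, start + win + 3))
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place protospacer for sp{spec.spacer_index}")
        if spec.target_strand == "viral":
            chunk = pam_inst + proto
            rep_from = start - len(pam_inst)
            proto_off = len(pam_inst)
        else:
            chunk = revcomp(proto) + (revcomp(pam_inst) if pam_inst else "")
            rep_from = start
            proto_off = 0
        plants.append({"from": rep_from, "win": len(pam_inst) + win,
                       "chunk": chunk, "proto_off": proto_off,
                       "proto_len": len(proto), "spec": spec,
                       "identity": identity, "gq": gq, "gs": gs,
                       "pam": pam_inst})

    # splice right-to-left so earlier coordinates stay valid
    plants.sort(key=lambda p: -p["from"])
    for p in plants:
        seq = seq[:p["from"]] + p["chunk"] + seq[p["from"] + p["win"]:]
    # coordinate shifts from net indels
    events = sorted((p["from"], len(p["chunk"]) - p["win"]) for p in plants)

    def shift(pos: int) -> int:
        return pos + sum(d for s, d in events if s < pos)

    for f in features:
        f.start, f.end = shift(f.start) if f.start else 0, shift(f.end)
    truths = []
    for p in sorted(plants, key=lambda p: p["from"]):
        # shift() uses strict <, so a plant's own delta is not applied to it
        s0 = shift(p["from"]) + p["proto_off"]
        truths.append(ProtospacerTruth(
            spacer_index=p["spec"].spacer_index, virus_id=virus_id,
            start=s0, end=s0 + p["proto_len"],
            strand="+" if p["spec"].target_strand == "viral" else "-",
            identity=p["identity"], gaps_in_query=p["gq"],
            gaps_in_subject=p["gs"], region=p["spec"].region,
            with_pam=p["spec"].with_pam, pam=p["pam"]))
    truths.sort(key=lambda t: t.spacer_index)

    seq = _scrub_spurious_motifs(rng, seq, config.nonanucleotide,
                                 features, truths)
    return seq, features, truths


def _scrub_spurious_motifs(rng, seq: str, motif: str, features, truths) -> str:
    """Remove chance occurrences of the origin motif so exactly one remains
    on the viral-sense strand (and none on the complementary strand),
    keeping planted elements and reading frames intact.
    """
    L = len(seq)
    nona_start = next(f.start for f in features if f.kind == "origin")
    protected = [(nona_start, nona_start + 9)]
    protected += [(t.start - 3, t.end + 3) for t in truths]
    genes = [(f.start, f.end) for f in features if f.kind == "gene"]

    def in_protected(i):
        return any(s <= i < e for s, e in protected)

    for _ in range(20):
        fwd = [p for p in find_motif(seq, motif, circular=True) if p != nona_start]
        rev = find_motif(revcomp(seq), motif, circular=True)
        rev_fwd = [(L - p - 9) % L for p in rev]
        spurious = fwd + rev_fwd
        if not spurious:
            return seq
        p = spurious[0]
        fixed = False
        for off in range(9):
            i = (p + off) % L
            if in_protected(i):
                continue
            for base in "ACGT":
                if base == seq[i]:
                    continue
                cand = seq[:i] + base + seq[i + 1:]
                # keep gene translation intact: no new in-frame stop
                bad = False
                for gs_, ge_ in genes:
                    if gs_ <= i < ge_ - 3:
                        cs = gs_ + ((i - gs_) // 3) * 3
                        if cand[cs:cs + 3] in _STOPS:
                            bad = True
                        break
                if bad:
                    continue
                still = [q for q in find_motif(cand, motif, circular=True)
                         if q != nona_start]
                still += find_motif(revcomp(cand), motif, circular=True)
                if len(still) < len(spurious):
                    seq = cand
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            warnings.warn("could not scrub a spurious origin motif")
            return seq
    return seq


def generate_virus_set(config: SimConfig, truth_spacers: list[str],
                       plant_sets: list[list[PlantSpec]],
                       ids: list[str] | None = None):
    """Generate one virus per plant set, each independently seeded from
    ``config.seed``.  Returns (list of (id, seq), features dict, truths list).
    """
    ids = ids or [f"virus{k + 1}" for k in range(len(plant_sets))]
    genomes, feats, truths = [], {}, []
    for k, (vid, plants) in enumerate(zip(ids, plant_sets)):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, k]))
        seq, f, t = generate_virus(config, truth_spacers, virus_id=vid,
                                   planted=plants, rng=rng)
        genomes.append((vid, seq))
        feats[vid] = f
        truths.extend(t)
    return genomes, feats, truths


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_ground_truth_tsv(truths: list[ProtospacerTruth], path) -> None:
    import pandas as pd
    rows = [asdict(t) for t in truths]
    pd.DataFrame(rows, columns=["spacer_index", "virus_id", "start", "end",
                                "strand", "identity", "gaps_in_query",
                                "gaps_in_subject", "region", "with_pam",
                                "pam"]).to_csv(path, sep="\t", index=False)


def write_config_yaml(config: SimConfig, path) -> None:
    d = asdict(config)
    d["spacer_len_range"] = list(d["spacer_len_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_config_yaml(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["spacer_len_range"] = tuple(d["spacer_len_range"])
    d["planted"] = [PlantSpec(**p) for p in d.get("planted", [])]
    return SimConfig(**d)
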