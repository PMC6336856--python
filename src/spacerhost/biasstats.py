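"""Statistics over spacer–protospacer matches.

Covers the strand-targeting question (do spacers preferentially target
the encapsidated viral ssDNA strand?), per-region target densities,
stop-codon usage profiles (amber/opal/ochre — amber is reassigned to
pyrrolysine in Methanomassiliicoccales, depleting its use as a
terminator), spacer-age identity decay, and the spacer × genome presence
matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .annotation import Feature
from .glocal import SpacerMatch

log = logging.getLogger(__name__)

_STOP_NAMES = {"TAG": "amber", "TGA": "opal", "TAA": "ochre"}


@dataclass
class StrandBiasResult:
    """One-sided exact binomial test for viral-strand targeting excess."""

    n_total: int
    n_viral: int
    n_complementary: int
    one_sided_p: float
    two_sided_p: float | None = None

    @property
    def complementary_percent(self) -> int:
        """Whole-percent share of complementary-strand targets."""
        return round(100 * self.n_complementary / self.n_total) if self.n_total else 0


def binomial_tail(n: int, k: int, p: float = 0.5) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return float(sum(math.comb(n, i) * p ** i * (1 - p) ** (n - i)
                     for i in range(k, n + 1)))


def strand_bias_test(n_total: int, n_viral: int,
                     two_sided: bool = False) -> StrandBiasResult:
    """Probability of a viral-strand bias this large or larger by chance.

    Exact binomial tail at p = 1/2, summed term by term (no normal
    approximation).  The one-sided direction is fixed toward viral-strand
    excess; a two-sided p (summing all outcomes at most as probable as the
    observed one) is computed on request.
    """
    if not (0 <= n_viral <= n_total):
        raise ValueError("need 0 <= n_viral <= n_total")
    p1 = binomial_tail(n_total, n_viral)
    p2 = None
    if two_sided:
        obs = math.comb(n_total, n_viral)
        p2 = float(sum(math.comb(n_total, i) for i in range(n_total + 1)
                       if math.comb(n_total, i) <= obs) / 2 ** n_total)
    return StrandBiasResult(n_total=n_total, n_viral=n_viral,
                            n_complementary=n_total - n_viral,
                            one_sided_p=p1, two_sided_p=p2)


def strand_bias_from_matches(matches: list[SpacerMatch],
                             per_spacer_best: bool = True) -> StrandBiasResult:
    """Run the strand-bias test on scan output.

    A "+" match means the protospacer lies on the viral-sense strand.
    With ``per_spacer_best`` each spacer contributes its best match once
    (the unit of the test is the spacer).
    """
    if per_spacer_best:
        from .glocal import best_match_per_spacer
        matches = best_match_per_spacer(matches)
    n_viral = sum(1 for m in matches if m.strand == "+")
    return strand_bias_test(len(matches), n_viral)


@dataclass
class RegionDensity:
    region: str
    n_targets: int
    length: int
    per_kb: float


def target_density(matches: list[SpacerMatch],
                   annotations: dict[str, list[Feature]] | list[Feature]
                   ) -> tuple[list[RegionDensity], dict[str, int]]:
    """Targets per annotated region and the coding/template strand split.

    ``annotations`` is a feature list (single genome) or a mapping from
    genome id to feature list.  Matches on genomes without annotation are
    counted under region "unknown".  The strand split counts gene hits
    whose protospacer lies on the gene's coding strand versus its template
    strand.
    """
    if isinstance(annotations, dict):
        get = annotations.get
    else:
        fixed = list(annotations)
        def get(_gid):
            return fixed

    region_counts: dict[str, int] = {}
    region_len: dict[str, int] = {}
    strand_split = {"coding": 0, "template": 0}
    for m in matches:
        feats = get(m.genome_id)
        if not feats:
            region_counts["unknown"] = region_counts.get("unknown", 0) + 1
            continue
        mid = (m.start + m.end) / 2
        glen = max(f.end for f in feats)
        mid = mid % glen if glen else mid
        hit = None
        for f in feats:
            if f.start <= mid < f.end:
                hit = f
                break
        name = hit.name if hit else "unknown"
        region_counts[name] = region_counts.get(name, 0) + 1
        if hit is not None and hit.kind == "gene":
            strand_split["coding" if m.strand == hit.strand else "template"] += 1
    # representative lengths: mean over genomes carrying the region name
    seen: dict[str, list[int]] = {}
    gids = {m.genome_id for m in matches}
    for gid in gids:
        for f in (get(gid) or []):
            seen.setdefault(f.name, []).append(f.length)
    out = []
    for name, cnt in sorted(region_counts.items()):
        lens = seen.get(name, [])
        mean_len = sum(lens) / len(lens) if lens else 0
        out.append(RegionDensity(region=name, n_targets=cnt,
                                 length=int(round(mean_len)),
                                 per_kb=cnt / (mean_len / 1000) if mean_len else float("nan")))
    return out, strand_split


@dataclass
class StopCodonProfile:
    """Terminal stop-codon usage for a CDS set."""

    label: str
    n_cds: int                  # CDS ending in a standard stop
    n_excluded: int             # CDS not ending in a standard stop
    counts: dict[str, int]      # amber/opal/ochre counts
    percentages: dict[str, float]


def stop_codon_profile(cds_sequences, label: str = "set") -> StopCodonProfile:
    """Classify the final codon of each CDS as amber (TAG), opal (TGA) or
    ochre (TAA); other endings are excluded from the denominator and
    logged.  Percentages are over stop-ending CDS.
    """
    cds_sequences = list(cds_sequences)
    if not cds_sequences:
        raise ValueError("empty CDS set")
    counts = {"amber": 0, "opal": 0, "ochre": 0}
    excluded = 0
    for seq in cds_sequences:
        s = str(seq).upper().replace("U", "T")
        if len(s) < 3:
            excluded += 1
            continue
        name = _STOP_NAMES.get(s[-3:])
        if name is None:
            excluded += 1
        else:
            counts[name] += 1
    n = sum(counts.values())
    if excluded:
        log.info("%s: %d CDS not ending in a standard stop excluded",
                 label, excluded)
    pct = {k: (100.0 * v / n if n else float("nan")) for k, v in counts.items()}
    return StopCodonProfile(label=label, n_cds=n, n_excluded=excluded,
                            counts=counts, percentages=pct)


@dataclass
class AgeStratum:
    """A named, inclusive spacer-index range (sp<lo>..sp<hi>)."""

    name: str
    lo: int
    hi: int

    def contains(self, index: int) -> bool:
        return self.lo <= index <= self.hi


#: Leader-distance strata used for the infection-history reading.
DEFAULT_STRATA = [AgeStratum("modern", 1, 9), AgeStratum("middle", 12, 27),
                  AgeStratum("ancient", 35, 72)]


@dataclass
class AgeIdentitySummary:
    stratum: str
    n_spacers: int
    min_identity: float
    mean_identity: float


def identity_by_age(matches: list[SpacerMatch],
                    strata: list[AgeStratum] | None = None
                    ) -> tuple[list[AgeIdentitySummary], bool]:
    """Best-match identity per age stratum and a decay flag.

    Spacers closer to the leader are younger; identity to their
    protospacers decays with age.  The flag is True when the
    leader-proximal stratum's mean identity exceeds the most distal one's.
    """
    strata = strata or DEFAULT_STRATA
    pairs = sorted({(a.lo, a.hi) for a in strata})
    for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
        if a2 <= b1:
            raise ValueError("strata ranges overlap")
    from .glocal import best_match_per_spacer
    best = {m.spacer_index: m.identity for m in best_match_per_spacer(matches)
            if m.spacer_index is not None}
    out = []
    for st in strata:
        vals = [ident for idx, ident in best.items() if st.contains(idx)]
        if not vals:
            log.warning("stratum %s is empty; omitted", st.name)
            continue
        out.append(AgeIdentitySummary(stratum=st.name, n_spacers=len(vals),
                                      min_identity=min(vals),
                                      mean_identity=sum(vals) / len(vals)))
    decay = bool(out) and len(out) >= 2 and out[0].mean_identity > out[-1].mean_identity
    return out, decay


def presence_matrix(matches: list[SpacerMatch],
                    spacers: list[str] | None = None) -> pd.DataFrame:
    """Spacer × genome matrix of best identities (NaN where absent).

    Rows are spacers (those in *spacers* when given — matchless ones get an
    all-empty row — otherwise all spacers seen in the match list), columns
    genomes; duplicate hits of a spacer in one genome keep the best identity.
    """
    rows: dict[tuple[str, str], float] = {}
    spacer_order: list[str] = list(spacers or [])
    genome_order: list[str] = []
    for m in matches:
        key = (m.spacer_id, m.genome_id)
        if m.spacer_id not in spacer_order:
            spacer_order.append(m.spacer_id)
        if m.genome_id not in genome_order:
            genome_order.append(m.genome_id)
        if key not in rows or m.identity > rows[key]:
            rows[key] = m.identity
    mat = pd.DataFrame(index=spacer_order, columns=genome_order, dtype=float)
    for (sp, gid), ident in rows.items():
        mat.loc[sp, gid] = ident
    mat.index.name = "spacer"
    mat.columns.name = "genome"
    return mat


def presence_marginals(mat: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(genomes-per-spacer row counts, targets-per-genome column counts)."""
    return mat.notna().sum(axis=1), mat.notna().sum(axis=0)
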