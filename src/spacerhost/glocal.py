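"""Query-global / subject-local ("glocal") affine-gap alignment.

The aligner answers the question a CRISPR spacer search asks: does the
*entire* spacer align somewhere inside a viral genome?  Subject-terminal
gaps are free (the alignment may start and end at any subject position)
but the query must be covered end to end — no clipping.  A plain local
(Smith–Waterman) mode is provided as a fallback for more diverged targets.

Scoring: match +1, mismatch −1, affine gaps where the first gapped base
costs 2 and each additional gapped base 1 (gap_open −2, gap_extend −1).
A gap of length g therefore costs 2 + (g − 1).

The dynamic programme is vectorised with numpy across a batch of
equal-length queries and across the subject axis; the within-row
dependency of the gap-in-query state is resolved with a running-maximum
prefix scan, which is exact for a constant extension cost.  Traceback is
done separately, on a small subject window around each reported hit, with
a plain scalar three-state (Gotoh) DP.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sequtil import encode, revcomp

NEG = -(10 ** 8)  # effectively -infinity for int32 DP


class AlignmentInputError(ValueError):
    """Raised for invalid aligner input (e.g. subject shorter than query)."""


class CalibrationError(ValueError):
    """Raised when the E-value model does not cover a query length."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme. Defaults are the spacer-search parameters."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    mode: str = "glocal"  # "glocal" | "local"

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.mode not in ("glocal", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def gap_cost(self, length: int) -> int:
        """Positive cost of a gap run: |open| for the first base, |extend| after."""
        if length <= 0:
            return 0
        return -self.gap_open + (length - 1) * (-self.gap_extend)


@dataclass
class Alignment:
    """One pairwise alignment of a full query against a subject region."""

    query_id: str
    subject_id: str
    subject_start: int  # 0-based half-open, on the oriented subject
    subject_end: int
    subject_strand: str  # "+" | "-"
    score: int
    aligned_query: str   # with "-" gap characters
    aligned_subject: str
    identity: float      # identical columns / all columns (gaps included)
    gaps_in_query: int
    gaps_in_subject: int

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)


@dataclass
class SpacerMatch:
    """A spacer↔protospacer hit: the pipeline's central record."""

    spacer_id: str
    genome_id: str
    strand: str          # relative to the genome's given (viral-sense) orientation
    start: int           # 0-based half-open on the forward genome; end may
    end: int             # exceed the genome length for origin-spanning hits
    score: int
    evalue: float
    identity: float
    gaps_in_query: int
    gaps_in_subject: int
    aligned_query: str
    aligned_subject: str
    mode: str = "glocal"
    spacer_index: int | None = None

    def to_dict(self) -> dict:
        return {
            "spacer": self.spacer_id,
            "spacer_index": self.spacer_index,
            "genome": self.genome_id,
            "strand": self.strand,
            "start": self.start,
            "end": self.end,
            "score": self.score,
            "evalue": self.evalue,
            "identity": self.identity,
            "gaps_q": self.gaps_in_query,
            "gaps_s": self.gaps_in_subject,
            "aligned_query": self.aligned_query,
            "aligned_subject": self.aligned_subject,
            "mode": self.mode,
        }


@dataclass
class SubjectGenome:
    """A search subject; smacovirus-like genomes are circular by default."""

    id: str
    seq: str
    circular: bool = True

    def __len__(self):
        return len(self.seq)


# ---------------------------------------------------------------------------
# vectorised DP
# ---------------------------------------------------------------------------

def batch_end_scores(queries_enc: np.ndarray, subject_enc: np.ndarray,
                     params: AlignmentParams) -> np.ndarray:
    """Best alignment score per subject end position, for a batch of queries.

    Parameters
    ----------
    queries_enc : (nq, m) uint8 array of equal-length encoded queries.
    subject_enc : (n,) uint8 encoded subject.

    Returns
    -------
    (nq, n) int32: entry [q, j] is the best score of an alignment of query q
    ending at subject position j+1 (exclusive end coordinate j+1).  In glocal
    mode the query is fully covered; in local mode the score is the best
    local alignment ending at that subject position.
    """
    nq, m = queries_enc.shape
    n = subject_enc.shape[0]
    go, ge = params.gap_open, params.gap_extend
    local = params.mode == "local"

    sub_row = subject_enc[None, :]  # (1, n)
    ext_w = np.arange(n + 1, dtype=np.int32) * (-ge)

    D_prev = np.zeros((nq, n + 1), dtype=np.int32)  # free start before row 1
    P_prev = np.full((nq, n + 1), NEG, dtype=np.int32)
    Q_prev = np.full((nq, n + 1), NEG, dtype=np.int32)

    best_local = np.full((nq, n), NEG, dtype=np.int32) if local else None

    for i in range(1, m + 1):
        qcol = queries_enc[:, i - 1][:, None]  # (nq, 1)
        sub_scores = np.where((qcol == sub_row) & (qcol < 4),
                              params.match, params.mismatch).astype(np.int32)

        best_prev = np.maximum(np.maximum(D_prev, P_prev), Q_prev)
        D = np.empty((nq, n + 1), dtype=np.int32)
        D[:, 0] = NEG
        diag = best_prev[:, :-1]
        if local:
            diag = np.maximum(diag, 0)  # alignment may restart anywhere
        D[:, 1:] = diag + sub_scores

        P = np.maximum(np.maximum(D_prev + go, Q_prev + go), P_prev + ge)

        # gap-in-query state: horizontal run starting after some column k < j
        B = np.maximum(D, P) + go
        run = np.maximum.accumulate(B + ext_w, axis=1)
        Q = np.empty((nq, n + 1), dtype=np.int32)
        Q[:, 0] = NEG
        Q[:, 1:] = run[:, :-1] - ext_w[:-1]

        if local:
            np.maximum(best_local, D[:, 1:], out=best_local)
        D_prev, P_prev, Q_prev = D, P, Q

    if local:
        return best_local
    return np.maximum(D_prev, P_prev)[:, 1:]


# ---------------------------------------------------------------------------
# scalar DP with traceback (used on small windows)
# ---------------------------------------------------------------------------

def _scalar_dp(q: np.ndarray, s: np.ndarray, params: AlignmentParams):
    """Full three-state DP tables for a (small) query/subject pair."""
    m, n = len(q), len(s)
    go, ge = params.gap_open, params.gap_extend
    local = params.mode == "local"
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    P = [[NEG] * (n + 1) for _ in range(m + 1)]
    Q = [[NEG] * (n + 1) for _ in range(m + 1)]
    D[0] = [0] * (n + 1)  # virtual start state: free subject prefix
    for i in range(1, m + 1):
        qi = q[i - 1]
        Di, Pi, Qi = D[i], P[i], Q[i]
        Dp, Pp, Qp = D[i - 1], P[i - 1], Q[i - 1]
        for j in range(n + 1):
            if j > 0:
                sc = params.match if (qi == s[j - 1] and qi < 4) else params.mismatch
                best = max(Dp[j - 1], Pp[j - 1], Qp[j - 1])
                if local:
                    best = max(best, 0)
                Di[j] = best + sc
            Pi[j] = max(Dp[j] + go, Qp[j] + go, Pp[j] + ge)
            if j > 0:
                Qi[j] = max(Di[j - 1] + go, Pi[j - 1] + go, Qi[j - 1] + ge)
    return D, P, Q


def _traceback(q: np.ndarray, s: np.ndarray, params: AlignmentParams,
               end_i: int, end_j: int, qstr: str, sstr: str):
    """Trace one optimal alignment ending at query row end_i, subject col end_j.

    Tie-break: prefer diagonal over gap-in-subject over gap-in-query.
    Returns (subject_start, aligned_query, aligned_subject, score).
    """
    D, P, Q = _scalar_dp(q, s, params)
    go, ge = params.gap_open, params.gap_extend
    local = params.mode == "local"
    i, j = end_i, end_j
    # end state: prefer diagonal, then gap-in-subject
    if D[i][j] >= P[i][j]:
        state, score = "D", D[i][j]
    else:
        state, score = "P", P[i][j]
    aq, asub = [], []
    while i > 0:
        if state == "D":
            val = D[i][j]
            sc = params.match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else params.mismatch
            prev = val - sc
            aq.append(qstr[i - 1])
            asub.append(sstr[j - 1])
            i, j = i - 1, j - 1
            if local and prev == 0 and (i == 0 or max(D[i][j], P[i][j], Q[i][j]) < 0):
                break  # local alignment start
            if i == 0:
                break
            for nxt in ("D", "P", "Q"):
                tab = {"D": D, "P": P, "Q": Q}[nxt]
                if tab[i][j] == prev:
                    state = nxt
                    break
            else:  # free glocal start on row 0 handled by i == 0 above
                raise AssertionError("traceback lost")
        elif state == "P":
            val = P[i][j]
            aq.append(qstr[i - 1])
            asub.append("-")
            if val == D[i - 1][j] + go:
                state = "D"
            elif val == P[i - 1][j] + ge:
                state = "P"
            else:
                state = "Q"
            i -= 1
            if i == 0:
                break
        else:  # Q: gap in query
            val = Q[i][j]
            aq.append("-")
            asub.append(sstr[j - 1])
            if val == D[i][j - 1] + go:
                state = "D"
            elif val == P[i][j - 1] + go:
                state = "P"
            else:
                state = "Q"
            j -= 1
    return j, "".join(reversed(aq)), "".join(reversed(asub)), score


def alignment_stats(aligned_query: str, aligned_subject: str) -> tuple[float, int, int]:
    """(identity, gaps_in_query, gaps_in_subject) from aligned strings.

    Identity counts identical non-gap columns over *all* columns.
    """
    cols = len(aligned_query)
    ident = sum(1 for a, b in zip(aligned_query, aligned_subject)
                if a == b and a != "-")
    gq = aligned_query.count("-")
    gs = aligned_subject.count("-")
    return (ident / cols if cols else 0.0), gq, gs


def score_alignment(aligned_query: str, aligned_subject: str,
                    params: AlignmentParams) -> int:
    """Re-score an alignment from its gapped strings (audit helper)."""
    score = 0
    prev_gap = None  # "q" | "s" | None
    for a, b in zip(aligned_query, aligned_subject):
        if a == "-":
            score += params.gap_extend if prev_gap == "q" else params.gap_open
            prev_gap = "q"
        elif b == "-":
            score += params.gap_extend if prev_gap == "s" else params.gap_open
            prev_gap = "s"
        else:
            score += params.match if (a == b and a in "ACGT") else params.mismatch
            prev_gap = None
    return score


# ---------------------------------------------------------------------------
# single-pair public API
# ---------------------------------------------------------------------------

def _align_at_end(query: str, subject: str, params: AlignmentParams,
                  end_j: int, end_score: int,
                  query_id: str = "query", subject_id: str = "subject",
                  strand: str = "+") -> Alignment:
    """Build the Alignment for a hit ending at subject position end_j."""
    m = len(query)
    # window large enough for any optimal alignment ending at end_j: the
    # subject span is at most m + (gaps in query); a span beyond 2m would
    # need > m query gaps, which can never be optimal at these costs.
    win_start = max(0, end_j - 2 * m - 4)
    q_enc = encode(query)
    s_win = subject[win_start:end_j]
    s_enc = encode(s_win)
    if params.mode == "local":
        D, P, Q = _scalar_dp(q_enc, s_enc, params)
        jl = len(s_win)
        end_i = max(range(1, m + 1), key=lambda i: D[i][jl])
    else:
        end_i = m
    start_local, aq, asub, score = _traceback(q_enc, s_enc, params,
                                              end_i, len(s_win), query, s_win)
    if score != end_score:
        raise AssertionError(
            f"traceback score {score} != DP score {end_score} at end {end_j}")
    ident, gq, gs = alignment_stats(aq, asub)
    return Alignment(query_id=query_id, subject_id=subject_id,
                     subject_start=win_start + start_local, subject_end=end_j,
                     subject_strand=strand, score=score,
                     aligned_query=aq, aligned_subject=asub,
                     identity=ident, gaps_in_query=gq, gaps_in_subject=gs)


def glocal_align(query: str, subject: str,
                 params: AlignmentParams | None = None) -> Alignment:
    """Best glocal alignment: full query vs a local subject region.

    The traceback starts from the maximal cell in the last query row; among
    equal-scoring end cells the smallest subject end coordinate wins.
    """
    params = params or AlignmentParams()
    if params.mode != "glocal":
        params = replace(params, mode="glocal")
    if len(subject) < len(query):
        raise AlignmentInputError("subject shorter than query")
    if not query:
        raise AlignmentInputError("empty query")
    ends = batch_end_scores(encode(query)[None, :], encode(subject), params)[0]
    end_j = int(np.argmax(ends)) + 1
    return _align_at_end(query, subject, params, end_j, int(ends[end_j - 1]))


def local_align(query: str, subject: str,
                params: AlignmentParams | None = None) -> Alignment | None:
    """Best local (Smith–Waterman) alignment; None when nothing scores > 0."""
    params = params or AlignmentParams()
    if params.mode != "local":
        params = replace(params, mode="local")
    if len(subject) < len(query):
        raise AlignmentInputError("subject shorter than query")
    ends = batch_end_scores(encode(query)[None, :], encode(subject), params)[0]
    best = int(ends.max())
    if best <= 0:
        return None
    end_j = int(np.argmax(ends)) + 1
    return _align_at_end(query, subject, params, end_j, best)


# ---------------------------------------------------------------------------
# database scan
# ---------------------------------------------------------------------------

def _as_query(sp) -> tuple[str, str, int | None]:
    """Normalise a query to (id, sequence, spacer_index)."""
    if hasattr(sp, "sequence"):
        idx = getattr(sp, "index", None)
        sid = getattr(sp, "id", None) or (f"sp{idx}" if idx is not None else "sp?")
        return sid, sp.sequence, idx
    sid, seq = sp
    idx = None
    if sid.startswith("sp") and sid[2:].isdigit():
        idx = int(sid[2:])
    return sid, seq, idx


def _as_genome(g) -> SubjectGenome:
    if isinstance(g, SubjectGenome):
        return g
    gid, seq = g[0], g[1]
    circ = g[2] if len(g) > 2 else True
    return SubjectGenome(gid, seq, circ)


def select_hit_ends(end_scores: np.ndarray, min_score: int, min_sep: int) -> list[int]:
    """Greedy non-overlapping selection of hit end positions.

    Candidates scoring at least *min_score* are taken best-first (ties by
    smaller end coordinate); a candidate within *min_sep* of an accepted end
    is suppressed.  Returns exclusive end coordinates (1-based ends).
    """
    js = np.nonzero(end_scores >= min_score)[0]
    if js.size == 0:
        return []
    order = np.lexsort((js, -end_scores[js]))
    accepted: list[int] = []
    for k in order:
        j = int(js[k])
        if all(abs(j - a) >= min_sep for a in accepted):
            accepted.append(j)
    return [j + 1 for j in accepted]


def scan(spacers, genomes, params: AlignmentParams | None = None,
         evalue_model=None, threshold: float = 0.01,
         target_db_nt: int | None = None, min_sep: int | None = None,
         threshold_overrides: dict[str, float] | None = None) -> list[SpacerMatch]:
    """Align every spacer against both strands of every genome.

    Circular genomes are searched across the origin (the subject is extended
    by a wrap-around margin; origin-spanning hits are reported once, with
    ``end`` past the genome length).  Matches with E-value at or below
    *threshold* are returned; per (spacer, genome, strand) overlapping hits
    keep only the best-scoring one.

    ``threshold_overrides`` maps spacer ids to a looser per-spacer cut-off
    (the sp22-style exception).
    """
    params = params or AlignmentParams()
    if evalue_model is None:
        raise CalibrationError("scan requires a calibrated E-value model")
    queries = [_as_query(s) for s in spacers]
    subjects = [_as_genome(g) for g in genomes]
    overrides = threshold_overrides or {}
    if target_db_nt is None:
        target_db_nt = 2 * sum(len(g) for g in subjects)

    # group queries by length so each batch shares one DP
    by_len: dict[int, list[tuple[str, str, int | None]]] = {}
    for q in queries:
        by_len.setdefault(len(q[1]), []).append(q)
    for L in by_len:
        if not evalue_model.covers(L):
            raise CalibrationError(f"E-value model not calibrated for query length {L}")

    matches: dict[tuple, SpacerMatch] = {}
    for genome in subjects:
        n = len(genome.seq)
        ext = 0
        for L, group in by_len.items():
            loosest = max([threshold] + [overrides.get(q[0], threshold) for q in group])
            min_score = evalue_model.score_threshold(L, loosest, target_db_nt)
            sep = min_sep if min_sep is not None else max(1, L // 2)
            if genome.circular:
                ext = min(n, 2 * L + 4)
            q_enc = np.stack([encode(q[1]) for q in group])
            for strand in "+-":
                s_str = genome.seq if strand == "+" else revcomp(genome.seq)
                s_full = s_str + (s_str[:ext] if genome.circular else "")
                if len(s_full) < L:
                    continue
                ends = batch_end_scores(q_enc, encode(s_full), params)
                for row, (sid, seq, sidx) in enumerate(group):
                    thr = overrides.get(sid, threshold)
                    for end_j in select_hit_ends(ends[row], min_score, sep):
                        score = int(ends[row, end_j - 1])
                        ev = evalue_model.evalue(L, score, target_db_nt)
                        if ev > thr:
                            continue
                        aln = _align_at_end(seq, s_full, params, end_j, score,
                                            query_id=sid, subject_id=genome.id,
                                            strand=strand)
                        start, end = aln.subject_start, aln.subject_end
                        if genome.circular and start >= n:
                            start, end = start - n, end - n
                        if strand == "-":  # map to forward coordinates
                            span = end - start
                            start = (n - end) % n
                            end = start + span
                        key = (sid, genome.id, strand, start % max(n, 1))
                        m = SpacerMatch(
                            spacer_id=sid, genome_id=genome.id, strand=strand,
                            start=start, end=end, score=score, evalue=ev,
                            identity=aln.identity,
                            gaps_in_query=aln.gaps_in_query,
                            gaps_in_subject=aln.gaps_in_subject,
                            aligned_query=aln.aligned_query,
                            aligned_subject=aln.aligned_subject,
                            mode=params.mode, spacer_index=sidx)
                        old = matches.get(key)
                        if old is None or m.score > old.score:
                            matches[key] = m
    out = sorted(matches.values(),
                 key=lambda m: (m.spacer_index if m.spacer_index is not None else 1 << 30,
                                m.spacer_id, m.genome_id, m.strand, m.start))
    return out


def check_frame_preservation(match: SpacerMatch, annotation=None) -> str:
    """Gap rule for coding-region hits: "ok" when the gap counts are equal in
    query and subject or differ by exactly three (a frame-preserving indel);
    otherwise "flagged".  With an annotation given, non-coding hits are "ok"
    by construction.
    """
    if annotation is not None:
        mid = (match.start + match.end) / 2
        in_cds = any(f.kind == "gene" and f.start <= mid < f.end
                     for f in annotation)
        if not in_cds:
            return "ok"
    dq, ds = match.gaps_in_query, match.gaps_in_subject
    if dq == ds or abs(dq - ds) == 3:
        return "ok"
    return "flagged"


def best_match_per_spacer(matches: list[SpacerMatch],
                          genome_order: list[str] | None = None) -> list[SpacerMatch]:
    """One representative per spacer: highest score, then lowest E-value,
    then first genome in input order."""
    rank = {g: i for i, g in enumerate(genome_order)} if genome_order else {}
    best: dict[str, SpacerMatch] = {}
    for m in matches:
        cur = best.get(m.spacer_id)
        if cur is None:
            best[m.spacer_id] = m
            continue
        key_new = (-m.score, m.evalue, rank.get(m.genome_id, 1 << 30))
        key_old = (-cur.score, cur.evalue, rank.get(cur.genome_id, 1 << 30))
        if key_new < key_old:
            best[m.spacer_id] = m
    return sorted(best.values(),
                  key=lambda m: (m.spacer_index if m.spacer_index is not None else 1 << 30,
                                 m.spacer_id))
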