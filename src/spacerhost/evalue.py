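"""Empirical E-value calibration and array-level combined significance.

Spacer queries are short (~36 nt), so analytic BLAST statistics do not
apply directly; instead the score distribution is measured per query
length by aligning random queries against random sequence.  The E-value
of a score S is the expected number of hits of score >= S in a database
of the target size:

    E_L(S) = [hits with score >= S in calibration] / (n_queries * calib_nt)
             * target_db_nt

Hits are counted with the same non-overlapping selection rule the real
scan uses, so the calibration measures exactly the quantity the scan
thresholds on.  Scores beyond the well-sampled empirical range are
extrapolated with an exponential (Gumbel-like) tail fitted to the
survival counts, which is what lets a 36-nt perfect match report an
E-value in the 1e-7 regime without astronomical replicate counts.

The combined array-level arithmetic mirrors the multiple-testing
reasoning for a whole CRISPR array: with n spacers tried, the chance of
k matches as good or better is about n^k times the product of their
E-values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .glocal import (AlignmentParams, CalibrationError, batch_end_scores,
                     select_hit_ends)


@dataclass
class LengthCalibration:
    """Empirical score tail for one query length."""

    length: int
    score_floor: int
    exceedance: np.ndarray      # N(s) for s = floor .. floor+len-1; hits >= s
    denominator: float          # n_replicates * calibration nt
    n_replicates: int
    calib_db_nt: int
    tail_lambda: float = float("nan")
    tail_log_a: float = float("nan")   # log N_fit(s) = tail_log_a - tail_lambda * s
    tail_reliable: bool = False
    fit_score_max: int = 0             # last score the empirical counts cover well

    @property
    def total_events(self) -> int:
        return int(self.exceedance[0]) if self.exceedance.size else 0

    def rate(self, score: float) -> float:
        """Expected hits with score >= *score*, per query per database nt."""
        s = int(math.ceil(score))
        if self.exceedance.size == 0:
            return 0.0
        if s <= self.score_floor:
            return self.total_events / self.denominator
        if s <= self.fit_score_max:
            return float(self.exceedance[s - self.score_floor]) / self.denominator
        if not self.tail_reliable:
            # conservative: freeze at the last well-sampled count
            idx = min(self.fit_score_max, self.score_floor + self.exceedance.size - 1)
            return float(self.exceedance[idx - self.score_floor]) / self.denominator
        fitted = math.exp(self.tail_log_a - self.tail_lambda * s)
        anchor = float(self.exceedance[self.fit_score_max - self.score_floor])
        return min(fitted, anchor) / self.denominator

    def rate_mid(self, score: float) -> float:
        """Mid-survival rate: geometric mean of the step rates at s and s+1.

        Scores are integers, so the plain survival function P(score >= s)
        overshoots at every threshold crossing; the mid-P convention keeps
        the realised hit rate at an E-value cut-off close to the nominal
        value instead of systematically below it.
        """
        s = int(math.ceil(score))
        if s <= self.score_floor:
            return self.rate(s)
        r1 = self.rate(s)
        r2 = self.rate(s + 1)
        if r1 <= 0:
            return 0.0
        if r2 <= 0:
            return r1
        return math.sqrt(r1 * r2)


@dataclass
class EvalueModel:
    """Per-query-length empirical score -> E-value map.

    E-values scale linearly with the searched database size, which is
    passed per call (both strands counted).
    """

    calibrations: dict[int, LengthCalibration] = field(default_factory=dict)
    params: AlignmentParams = field(default_factory=AlignmentParams)
    seed: int = 0

    def covers(self, length: int) -> bool:
        return length in self.calibrations

    def evalue(self, length: int, score: float, target_db_nt: int) -> float:
        try:
            cal = self.calibrations[length]
        except KeyError:
            raise CalibrationError(
                f"no calibration for query length {length}") from None
        return cal.rate_mid(score) * target_db_nt

    def score_threshold(self, length: int, evalue_threshold: float,
                        target_db_nt: int) -> int:
        """Smallest integer score whose E-value is at or below the threshold.

        Returns a score above the best achievable one (so no hit can pass)
        when even a perfect match would not reach the threshold.
        """
        if evalue_threshold <= 0:
            raise ValueError("threshold must be positive")
        cal = self.calibrations.get(length)
        if cal is None:
            raise CalibrationError(f"no calibration for query length {length}")
        max_score = length * self.params.match
        for s in range(cal.score_floor, max_score + 1):
            if self.evalue(length, s, target_db_nt) <= evalue_threshold:
                return s
        return max_score + 1

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "params": {"match": self.params.match, "mismatch": self.params.mismatch,
                       "gap_open": self.params.gap_open,
                       "gap_extend": self.params.gap_extend},
            "lengths": {
                str(L): {
                    "score_floor": c.score_floor,
                    "exceedance": c.exceedance.tolist(),
                    "denominator": c.denominator,
                    "n_replicates": c.n_replicates,
                    "calib_db_nt": c.calib_db_nt,
                    "tail_lambda": c.tail_lambda,
                    "tail_log_a": c.tail_log_a,
                    "tail_reliable": c.tail_reliable,
                    "fit_score_max": c.fit_score_max,
                } for L, c in self.calibrations.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalueModel":
        params = AlignmentParams(**d["params"])
        model = cls(params=params, seed=d.get("seed", 0))
        for Ls, c in d["lengths"].items():
            model.calibrations[int(Ls)] = LengthCalibration(
                length=int(Ls), score_floor=c["score_floor"],
                exceedance=np.asarray(c["exceedance"], dtype=np.int64),
                denominator=c["denominator"], n_replicates=c["n_replicates"],
                calib_db_nt=c["calib_db_nt"], tail_lambda=c["tail_lambda"],
                tail_log_a=c["tail_log_a"], tail_reliable=c["tail_reliable"],
                fit_score_max=c["fit_score_max"])
        return model

    @classmethod
    def from_json(cls, path) -> "EvalueModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_tail(scores: np.ndarray, counts: np.ndarray, min_count: int = 10
              ) -> tuple[float, float, bool, int]:
    """Exponential tail from the deepest decade of the survival counts.

    The log-survival of glocal scores is concave (the decay steepens
    toward its asymptote), so a fit over the whole curve flattens the tail
    and inflates extrapolated E-values.  Instead the decay rate comes from
    the deepest well-sampled decade: the last score s2 with at least
    *min_count* exceedances and the last score s1 whose count is at least
    ten times larger.  The extrapolation is anchored exactly at s2, so the
    empirical table and the tail join continuously.
    """
    idx = np.nonzero(counts >= min_count)[0]
    if idx.size == 0:
        return float("nan"), float("nan"), False, int(scores[0])
    i2 = int(idx[-1])
    s2, n2 = float(scores[i2]), float(counts[i2])
    cand = np.nonzero(counts >= 10 * n2)[0]
    cand = cand[cand < i2]
    if cand.size == 0:
        return float("nan"), float("nan"), False, int(s2)
    i1 = int(cand[-1])
    s1, n1 = float(scores[i1]), float(counts[i1])
    lam = math.log(n1 / n2) / (s2 - s1)
    log_a = math.log(n2) + lam * s2
    return lam, log_a, bool(lam > 0.05), int(s2)


def calibrate(lengths, params: AlignmentParams | None = None,
              calib_db_nt: int = 1_000_000, n_replicates: int = 500,
              seed: int = 0, subject_chunk: int = 10_000,
              score_floor: int = 6) -> EvalueModel:
    """Build an empirical E-value model for the given query lengths.

    For each length, *n_replicates* i.i.d. uniform random queries are glocal
    aligned against i.i.d. uniform random subjects totalling *calib_db_nt*
    nucleotides; per-score exceedance counts of scan-style hits form the
    empirical tail, extended by an exponential fit.  Deterministic under
    *seed*.
    """
    params = params or AlignmentParams()
    model = EvalueModel(params=params, seed=seed)
    if isinstance(lengths, int):
        lengths = [lengths]
    for L in sorted(set(int(x) for x in lengths)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, L]))
        queries = rng.integers(0, 4, size=(n_replicates, L), dtype=np.uint8)
        n_chunks = max(1, math.ceil(calib_db_nt / subject_chunk))
        total_nt = n_chunks * subject_chunk
        max_score = L * params.match
        hist = np.zeros(max_score - score_floor + 1, dtype=np.int64)
        sep = max(1, L // 2)
        for _ in range(n_chunks):
            subject = rng.integers(0, 4, size=subject_chunk, dtype=np.uint8)
            ends = batch_end_scores(queries, subject, params)
            for row in range(n_replicates):
                for end_j in select_hit_ends(ends[row], score_floor, sep):
                    s = int(ends[row, end_j - 1])
                    hist[min(s, max_score) - score_floor] += 1
        exceed = hist[::-1].cumsum()[::-1]
        scores = np.arange(score_floor, max_score + 1)
        lam, log_a, reliable, fit_max = _fit_tail(scores, exceed)
        model.calibrations[L] = LengthCalibration(
            length=L, score_floor=score_floor, exceedance=exceed,
            denominator=float(n_replicates) * total_nt,
            n_replicates=n_replicates, calib_db_nt=total_nt,
            tail_lambda=lam, tail_log_a=log_a, tail_reliable=reliable,
            fit_score_max=fit_max)
    return model


def combined_array_significance(evalues, n_spacers: int) -> float:
    """Array-level significance: n_spacers ** k times the product of the k
    per-match E-values.  An empty list gives 1.0; values above 1 are
    reported as-is.
    """
    evalues = list(evalues)
    if not evalues:
        return 1.0
    if any(e > 1 for e in evalues):
        import warnings
        warnings.warn("E-values above 1 passed to combined_array_significance")
    prod = math.prod(evalues)
    return float(n_spacers ** len(evalues) * prod)


def expected_random_matches(n_queries: int, threshold: float) -> float:
    """Expected chance matches for n queries at an E-value threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(n_queries * threshold)
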