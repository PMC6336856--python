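"""Independent alignment oracles used to validate the production DP.

Two layers: ``enumerate_glocal_score`` exhaustively enumerates alignment
column strings (feasible only for tiny inputs) and scores them with its
own scorer; ``recursive_glocal_score`` / ``recursive_local_score`` are
plain memoised scalar recursions, validated against the enumeration and
then used as the oracle for larger random instances.  Nothing here shares
code with the vectorised implementation under test.
"""

from __future__ import annotations

import functools

NEG = -(10 ** 7)


def score_columns(aq: str, asub: str, match=1, mismatch=-1, gap_open=-2,
                  gap_extend=-1) -> int:
    total = 0
    prev = None
    for a, b in zip(aq, asub):
        if a == "-":
            total += gap_extend if prev == "q" else gap_open
            prev = "q"
        elif b == "-":
            total += gap_extend if prev == "s" else gap_open
            prev = "s"
        else:
            total += match if a == b else mismatch
            prev = None
    return total


def enumerate_glocal_score(q: str, s: str, **kw) -> int:
    """Max score over every alignment of the full query against every
    subject window, generated explicitly.  Exponential; keep q <= 5, s <= 8.
    """
    best = NEG
    n = len(s)
    for a in range(n + 1):
        for b in range(a, n + 1):
            win = s[a:b]
            stack = [(0, 0, "", "")]
            while stack:
                i, j, aq, asub = stack.pop()
                if i == len(q) and j == len(win):
                    sc = score_columns(aq, asub, **kw)
                    if sc > best:
                        best = sc
                    continue
                if i < len(q) and j < len(win):
                    stack.append((i + 1, j + 1, aq + q[i], asub + win[j]))
                if i < len(q):
                    stack.append((i + 1, j, aq + q[i], asub + "-"))
                if j < len(win):
                    stack.append((i, j + 1, aq + "-", asub + win[j]))
    return best


def recursive_glocal_score(q: str, s: str, match=1, mismatch=-1, gap_open=-2,
                           gap_extend=-1) -> int:
    """Memoised scalar recursion for the glocal score (full query, free
    subject ends)."""

    @functools.lru_cache(maxsize=None)
    def f(i: int, j: int, state: str) -> int:
        if i == 0:
            return 0 if state == "start" else NEG
        if state == "start":
            return NEG  # the free start exists only before the first query base
        if state == "D":
            if j == 0:
                return NEG
            sub = match if q[i - 1] == s[j - 1] else mismatch
            return max(f(i - 1, j - 1, st) for st in ("D", "P", "Q", "start")) + sub
        if state == "P":
            return max(f(i - 1, j, "D") + gap_open,
                       f(i - 1, j, "P") + gap_extend,
                       f(i - 1, j, "Q") + gap_open,
                       f(i - 1, j, "start") + gap_open)
        if state == "Q":
            if j == 0:
                return NEG
            return max(f(i, j - 1, "D") + gap_open,
                       f(i, j - 1, "P") + gap_open,
                       f(i, j - 1, "Q") + gap_extend)
        raise AssertionError(state)

    m, n = len(q), len(s)
    return max(f(m, j, st) for j in range(n + 1) for st in ("D", "P"))


def recursive_global_score(q: str, s: str, match=1, mismatch=-1, gap_open=-2,
                           gap_extend=-1) -> int:
    """Needleman–Wunsch with affine gaps: both sequences fully consumed."""

    @functools.lru_cache(maxsize=None)
    def f(i: int, j: int, state: str) -> int:
        if i == 0 and j == 0:
            return 0 if state == "start" else NEG
        if state == "start":
            return NEG
        if i == 0:
            if state != "Q":
                return NEG
            return (gap_open if j == 1
                    else f(0, j - 1, "Q") + gap_extend)
        if state == "D":
            if j == 0:
                return NEG
            sub = match if q[i - 1] == s[j - 1] else mismatch
            return max(f(i - 1, j - 1, st) for st in ("D", "P", "Q", "start")) + sub
        if state == "P":
            return max(f(i - 1, j, "D") + gap_open,
                       f(i - 1, j, "P") + gap_extend,
                       f(i - 1, j, "Q") + gap_open,
                       f(i - 1, j, "start") + gap_open)
        if state == "Q":
            if j == 0:
                return NEG
            return max(f(i, j - 1, "D") + gap_open,
                       f(i, j - 1, "P") + gap_open,
                       f(i, j - 1, "Q") + gap_extend,
                       f(i, j - 1, "start") + gap_open)
        raise AssertionError(state)

    return max(f(len(q), len(s), st) for st in ("D", "P", "Q"))


def recursive_local_score(q: str, s: str, match=1, mismatch=-1, gap_open=-2,
                          gap_extend=-1) -> int:
    """Smith–Waterman score by scalar recurrence (0 when nothing positive)."""
    m, n = len(q), len(s)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
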