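"""Global affine-gap alignment (Gotoh three-matrix DP) with deterministic
traceback.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(the open penalty is charged once per gap opening; a deletion run directly
following an insertion run opens a new gap). Defaults are long-read-ish:
match +2, mismatch -4, gap_open -4, gap_extend -2.

Traceback tie-break order is match/mismatch > deletion > insertion, so
CIGARs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._seq import check_dna, encode

__all__ = ["AlignParams", "AffineAlignment", "global_align_affine"]

NEG_INF = -1e18

# op codes used in cigars
OP_MATCH = "M"  # match or mismatch (consumes query and reference)
OP_INS = "I"  # insertion: present in query, absent in reference
OP_DEL = "D"  # deletion: absent in query, present in reference


@dataclass(frozen=True)
class AlignParams:
    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -4.0
    gap_extend: float = -2.0


@dataclass
class AffineAlignment:
    """An optimal global alignment as run-length CIGAR operations."""

    cigar: list[tuple[str, int]]
    score: float
    params: AlignParams

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in (OP_MATCH, OP_INS))

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if op in (OP_MATCH, OP_DEL))


@njit(cache=False)
def _gotoh(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = q.size, r.size
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in reference (insertion, consumes query)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in query (deletion, consumes reference)
    # pointers: which matrix the max came from (0=M, 1=Y, 2=X); -1 unset
    pM = np.full((n + 1, m + 1), -1, dtype=np.int8)
    pX = np.full((n + 1, m + 1), -1, dtype=np.int8)
    pY = np.full((n + 1, m + 1), -1, dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * i
        pX[i, 0] = 0 if i == 1 else 2
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * j
        pY[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            # M: prefer M > Y(deletion) > X(insertion) on ties
            best = M[i - 1, j - 1]
            ptr = 0
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 1
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pM[i, j] = ptr
            # X: insertion ending at q[i-1]
            best = M[i - 1, j] + gap_open + gap_extend
            ptr = 0
            cand = Y[i - 1, j] + gap_open + gap_extend
            if cand > best:
                best = cand
                ptr = 1
            cand = X[i - 1, j] + gap_extend
            if cand > best:
                best = cand
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr
            # Y: deletion ending at r[j-1]
            best = M[i, j - 1] + gap_open + gap_extend
            ptr = 0
            cand = Y[i, j - 1] + gap_extend
            if cand > best:
                best = cand
                ptr = 1
            cand = X[i, j - 1] + gap_open + gap_extend
            if cand > best:
                best = cand
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr

    # final state: prefer M > Y > X on ties
    state = 0
    score = M[n, m]
    if Y[n, m] > score:
        score = Y[n, m]
        state = 1
    if X[n, m] > score:
        score = X[n, m]
        state = 2

    ops = np.empty(n + m, dtype=np.int8)  # 0=M, 1=I, 2=D
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                # only possible at origin
                break
            ops[k] = 0
            k += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 2:  # X: insertion
            ops[k] = 1
            k += 1
            state = pX[i, j]
            # pointer codes: 0=M,1=Y,2=X
            i -= 1
        else:  # Y: deletion
            ops[k] = 2
            k += 1
            state = pY[i, j]
            j -= 1
    return score, ops[:k][::-1].copy()


def global_align_affine(
    query: str, reference: str, params: AlignParams = AlignParams()
) -> AffineAlignment:
    """Optimal global alignment of ``query`` against ``reference``."""
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    q = encode(check_dna(query, "query"))
    r = encode(check_dna(reference, "reference"))
    score, ops = _gotoh(
        q, r, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    cigar: list[tuple[str, int]] = []
    codes = "MID"
    for o in ops:
        op = codes[o]
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    aln = AffineAlignment(cigar=cigar, score=float(score), params=params)
    if aln.query_length != len(query) or aln.reference_length != len(reference):
        raise AssertionError("cigar does not reconstruct input lengths")
    return aln
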