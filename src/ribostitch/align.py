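"""Shared pairwise-alignment primitives.

A fast vectorized ungapped comparison is the common path; a banded
affine-gap (Gotoh) aligner is the fallback when indels are suspected.
Scoring defaults: match +1, mismatch -1, gap open -3 (first gap base),
gap extend -1 per additional base.
"""

from __future__ import annotations

import dataclasses

import numpy as np

NEG_INF = -(10 ** 9)


def encode(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array for vectorized comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def ungapped_matches(a: np.ndarray, b: np.ndarray) -> int:
    """Number of equal positions between equal-length encoded sequences."""
    return int(np.count_nonzero(a == b))


@dataclasses.dataclass
class AlignResult:
    score: int
    cigar: list[tuple[str, int]]  # ops over {M, I, D, S}; I consumes query only
    matches: int
    columns: int                  # aligned columns = M + I + D

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def cigar_query_length(cigar) -> int:
    return sum(n for op, n in cigar if op in "MIS")


def cigar_ref_length(cigar) -> int:
    return sum(n for op, n in cigar if op in "MD")


def cigar_to_string(cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def _compress(ops: list[str]) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return cigar


def banded_global(
    query: str,
    ref: str,
    band: int = 15,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -3,
    gap_extend: int = -1,
) -> AlignResult:
    """Global banded affine-gap alignment of ``query`` against ``ref``.

    The band is centred on the main diagonal and widened automatically to
    accommodate the length difference. Suitable for near-identical
    sequences; cost is O(len(query) * band).
    """
    n, m = len(query), len(ref)
    if n == 0 or m == 0:
        ops = [("I", n)] if n else [("D", m)]
        cols = n + m
        score = gap_open + gap_extend * (cols - 1) if cols else 0
        return AlignResult(score, [o for o in ops if o[1]], 0, cols)
    lo_d = min(0, m - n) - band
    hi_d = max(0, m - n) + band
    width = hi_d - lo_d + 1

    # state 0 = M (diagonal), 1 = I (gap in ref, consume query), 2 = D
    score_prev = [[NEG_INF] * width for _ in range(3)]
    tb = np.zeros((n + 1, width, 3), dtype=np.uint8)  # packed previous-state

    def col(i: int, j: int) -> int:
        return j - i - lo_d

    # row 0: only D moves along ref
    c0 = col(0, 0)
    score_prev[0][c0] = 0
    for j in range(1, min(m, hi_d) + 1):
        c = col(0, j)
        score_prev[2][c] = gap_open + gap_extend * (j - 1)
        tb[0, c, 2] = 2 if j > 1 else 0

    q = query
    r = ref
    for i in range(1, n + 1):
        score_cur = [[NEG_INF] * width for _ in range(3)]
        j_lo = max(0, i + lo_d)
        j_hi = min(m, i + hi_d)
        qc = q[i - 1]
        row_m, row_i, row_d = score_cur
        prev_m, prev_i, prev_d = score_prev
        for j in range(j_lo, j_hi + 1):
            c = j - i - lo_d
            # I: consume query only; from row i-1, same j => column c+1 in prev row
            ci = c + 1
            if ci < width:
                open_m = prev_m[ci] + gap_open
                ext_i = prev_i[ci] + gap_extend
                open_d = prev_d[ci] + gap_open
                best = open_m
                state = 0
                if ext_i > best:
                    best, state = ext_i, 1
                if open_d > best:
                    best, state = open_d, 2
                if best > NEG_INF // 2:
                    row_i[c] = best
                    tb[i, c, 1] = state
            if j > 0:
                # M: diagonal from (i-1, j-1) => same column c in prev row
                sub = match if qc == r[j - 1] else mismatch
                bm = prev_m[c]
                bi = prev_i[c]
                bd = prev_d[c]
                best = bm
                state = 0
                if bi > best:
                    best, state = bi, 1
                if bd > best:
                    best, state = bd, 2
                if best > NEG_INF // 2:
                    row_m[c] = best + sub
                    tb[i, c, 0] = state
                # D: consume ref only; from (i, j-1) => column c-1, same row
                if c - 1 >= 0:
                    open_m = row_m[c - 1] + gap_open
                    ext_d = row_d[c - 1] + gap_extend
                    open_i = row_i[c - 1] + gap_open
                    best = open_m
                    state = 0
                    if open_i > best:
                        best, state = open_i, 1
                    if ext_d > best:
                        best, state = ext_d, 2
                    if best > NEG_INF // 2:
                        row_d[c] = best
                        tb[i, c, 2] = state
        score_prev = score_cur

    c_end = col(n, m)
    finals = [score_prev[s][c_end] for s in range(3)]
    state = int(np.argmax(finals))
    final_score = finals[state]
    if final_score <= NEG_INF // 2:
        raise ValueError("band too narrow for global alignment")

    # traceback
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        c = j - i - lo_d
        prev_state = int(tb[i, c, state])
        if state == 0:
            ops.append("M")
            i -= 1
            j -= 1
        elif state == 1:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
        state = prev_state
        if i == 0 and j == 0:
            break
    ops.reverse()
    cigar = _compress(ops)

    matches = 0
    qi = ri = 0
    for op, length in cigar:
        if op == "M":
            for t in range(length):
                if query[qi + t] == ref[ri + t]:
                    matches += 1
            qi += length
            ri += length
        elif op == "I":
            qi += length
        else:
            ri += length
    columns = sum(length for _, length in cigar)
    return AlignResult(int(final_score), cigar, matches, columns)


def place_ungapped(
    query: np.ndarray, ref: np.ndarray, offset: int
) -> tuple[int, int, int, int]:
    """Compare ``query`` laid on ``ref`` at ``offset`` without gaps.

    Returns (matches, overlap_length, query_start, query_end): the query
    sub-interval that falls inside the reference and its match count.
    Out-of-bounds overhang becomes soft clip in the caller.
    """
    n, m = len(query), len(ref)
    q_start = max(0, -offset)
    q_end = min(n, m - offset)
    if q_end <= q_start:
        return 0, 0, 0, 0
    seg_q = query[q_start:q_end]
    seg_r = ref[offset + q_start: offset + q_end]
    return ungapped_matches(seg_q, seg_r), q_end - q_start, q_start, q_end
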