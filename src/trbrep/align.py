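"""Local nucleotide alignment with a fixed, unit-testable scoring scheme.

Scoring: match +1, mismatch -1, linear gap -2; ``N`` mismatches everything.
``align_segment`` returns the maximal-scoring local alignment; among equally
scoring alignments the one with the smallest ``read_start`` wins, then the
smallest ``segment_start``, then the smallest end coordinates.  This makes
results exactly reproducible and directly comparable to a brute-force
enumeration over all substring pairs.

The tie-break is implemented with two dynamic-programming passes instead of
a single traceback: a suffix pass finds the best score attainable by an
alignment *starting* at each cell (an optimal local alignment never starts
or ends with a gap or mismatch, so scanning for the first cell achieving
the global maximum yields the minimal start), and an anchored forward pass
from that start finds the minimal end.  Kernels are numba-compiled; a
pure-Python oracle for them lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["AlignmentHit", "align_segment", "encode_nt", "best_scores"]

MATCH, MISMATCH, GAP = 1, -1, -2
_NEG = -(10**9)

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode_nt(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a read against a germline segment.

    Coordinates are 0-based, half-open on both sequences.
    """

    segment_id: str
    score: int
    read_start: int
    read_end: int
    segment_start: int
    segment_end: int


@njit(cache=True)
def _score_and_start(r, s):  # pragma: no cover - numba
    """Max local-alignment score and its lexicographically smallest start.

    T[i, j] = best score of an alignment continuing from (i, j), allowed to
    stop at any point (clamped at 0: an optimal alignment has no
    negative-scoring suffix).  The score of the best alignment whose first
    column consumes (read[i], seg[j]) is sub(i, j) + T[i+1, j+1]; optimal
    alignments always begin with an aligned pair, so scanning cells in
    (i, j) order for the first one achieving the maximum gives the minimal
    (read_start, segment_start).
    """
    n, m = len(r), len(s)
    T = np.zeros((n + 1, m + 1), dtype=np.int32)
    best = 0
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            sub = MATCH if (r[i] == s[j] and r[i] < 4) else MISMATCH
            v = sub + T[i + 1, j + 1]
            w = T[i + 1, j] + GAP
            if w > v:
                v = w
            w = T[i, j + 1] + GAP
            if w > v:
                v = w
            if v > best:
                best = v
            T[i, j] = v if v > 0 else 0
    if best <= 0:
        return 0, -1, -1
    for i in range(n):
        for j in range(m):
            sub = MATCH if (r[i] == s[j] and r[i] < 4) else MISMATCH
            if sub + T[i + 1, j + 1] == best:
                return best, i, j
    return best, -1, -1  # unreachable


@njit(cache=True)
def _end_from_start(r, s, rs, ss, target):  # pragma: no cover - numba
    """Smallest (read_end, segment_end) of a score-`target` alignment from (rs, ss)."""
    n, m = len(r) - rs, len(s) - ss
    D = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    sub0 = MATCH if (r[rs] == s[ss] and r[rs] < 4) else MISMATCH
    D[1, 1] = sub0
    for j in range(2, m + 1):
        D[1, j] = D[1, j - 1] + GAP
    for i in range(2, n + 1):
        D[i, 1] = D[i - 1, 1] + GAP
        for j in range(2, m + 1):
            sub = MATCH if (r[rs + i - 1] == s[ss + j - 1] and r[rs + i - 1] < 4) else MISMATCH
            v = D[i - 1, j - 1] + sub
            w = D[i - 1, j] + GAP
            if w > v:
                v = w
            w = D[i, j - 1] + GAP
            if w > v:
                v = w
            D[i, j] = v
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if D[i, j] == target:
                return rs + i, ss + j
    return -1, -1  # unreachable for a valid target


@njit(cache=True)
def _traceback_map(r, s, rs, ss, re, se):  # pragma: no cover - numba
    """Map segment positions [ss, se) to read positions (-1 where gapped).

    Recomputes the anchored DP and walks back from (re, se) preferring
    diagonal, then read-gap, then segment-gap moves (deterministic when
    several optimal paths exist; the path is unique for exact matches).
    """
    n, m = re - rs, se - ss
    D = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    sub0 = MATCH if (r[rs] == s[ss] and r[rs] < 4) else MISMATCH
    D[1, 1] = sub0
    for j in range(2, m + 1):
        D[1, j] = D[1, j - 1] + GAP
    for i in range(2, n + 1):
        D[i, 1] = D[i - 1, 1] + GAP
        for j in range(2, m + 1):
            sub = MATCH if (r[rs + i - 1] == s[ss + j - 1] and r[rs + i - 1] < 4) else MISMATCH
            v = D[i - 1, j - 1] + sub
            w = D[i - 1, j] + GAP
            if w > v:
                v = w
            w = D[i, j - 1] + GAP
            if w > v:
                v = w
            D[i, j] = v
    seg2read = np.full(len(s), -1, dtype=np.int64)
    i, j = n, m
    while i > 0 and j > 0:
        if i == 1 and j == 1:
            seg2read[ss] = rs
            break
        sub = MATCH if (r[rs + i - 1] == s[ss + j - 1] and r[rs + i - 1] < 4) else MISMATCH
        if i > 1 and j > 1 and D[i, j] == D[i - 1, j - 1] + sub:
            seg2read[ss + j - 1] = rs + i - 1
            i -= 1
            j -= 1
        elif i > 1 and D[i, j] == D[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
    return seg2read


@njit(cache=True)
def _best_scores(r, segs, seg_lens):  # pragma: no cover - numba
    out = np.zeros(segs.shape[0], dtype=np.int32)
    for k in range(segs.shape[0]):
        sc, _, _ = _score_and_start(r, segs[k, : seg_lens[k]])
        out[k] = sc
    return out


def best_scores(read_codes: np.ndarray, seg_matrix: np.ndarray, seg_lens: np.ndarray) -> np.ndarray:
    """Best local-alignment score of a read against each padded segment row."""
    if len(read_codes) == 0:
        return np.zeros(seg_matrix.shape[0], dtype=np.int32)
    return _best_scores(read_codes, seg_matrix, seg_lens)


def align_segment(read_nt: str, segment) -> AlignmentHit:
    """Maximal-scoring local alignment of ``read_nt`` against a germline segment.

    ``segment`` is a :class:`~trbrep.germline.GermlineSegment` (or any object
    with ``id`` and ``seq_nt``).  A best score of 0 means "no hit": the hit
    is returned with score 0 and empty coordinates.
    """
    if not read_nt or not segment.seq_nt:
        raise ValueError("both sequences must be nonempty")
    r, s = encode_nt(read_nt), encode_nt(segment.seq_nt)
    score, rs, ss = _score_and_start(r, s)
    if score <= 0:
        return AlignmentHit(segment.id, 0, 0, 0, 0, 0)
    re_, se = _end_from_start(r, s, rs, ss, score)
    return AlignmentHit(segment.id, int(score), int(rs), int(re_), int(ss), int(se))


def alignment_read_position(read_nt: str, segment, hit: AlignmentHit, seg_pos: int) -> int:
    """Read position aligned to ``seg_pos`` under ``hit`` (-1 if gapped/outside)."""
    if not (hit.segment_start <= seg_pos < hit.segment_end):
        return -1
    r, s = encode_nt(read_nt), encode_nt(segment.seq_nt)
    seg2read = _traceback_map(
        r, s, hit.read_start, hit.segment_start, hit.read_end, hit.segment_end
    )
    return int(seg2read[seg_pos])
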