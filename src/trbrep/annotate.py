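"""V(D)J segment assignment, CDR3 junction extraction, and clonotype assembly.

For each QC-passed read the best-scoring V segment is called first; the J
segment is then aligned against the read suffix beyond the V alignment, so
``j.read_start >= v.read_end`` holds by construction.  Score ties between
segments break to the lexicographically smaller id; a read with either
best score below ``min_score`` (default 10) is a no-call.

The CDR3 junction is anchor-inclusive: from the first base of the V
segment's conserved second-cysteine codon through the last base of the J
segment's conserved phenylalanine codon, so a productive junction starts
with C and ends with F, and reported lengths match the junction_aa
convention (the study design this package emulates reports mean lengths
near 14 aa, which is the anchor-inclusive scale).  D segments are too
short for scored alignment to be reliable and are assigned by longest
exact substring match (>= 5 nt) inside the junction, ties yielding no
call.  Only the forward strand is searched by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .align import (
    AlignmentHit,
    align_segment,
    alignment_read_position,
    best_scores,
    encode_nt,
)
from .germline import GermlineSegment, Reference, SegmentKind, translate_nt
from .io import SequenceRead

__all__ = [
    "Annotation",
    "Repertoire",
    "AnnotationEngine",
    "assign_vj",
    "extract_cdr3",
    "assign_d",
    "is_productive",
    "build_repertoire",
    "annotate_reads",
]

DEFAULT_MIN_SCORE = 10


@dataclass(frozen=True)
class Annotation:
    """Per-read V/D/J calls, CDR3 sequences, and productivity."""

    read_id: str
    v_call: str
    j_call: str
    d_call: str | None
    cdr3_nt: str | None
    cdr3_aa: str | None
    productive: bool
    v_score: int
    j_score: int


@dataclass
class Repertoire:
    """One sample's clonotype table plus metadata.

    ``clonotypes`` has columns cdr3_aa, v_call, d_call, j_call, count,
    frequency; the clonotype key is (cdr3_aa, v_call, j_call), with
    ``d_call`` the most frequent D call among the clonotype's reads.
    """

    sample_id: str
    group: str | None
    clonotypes: pd.DataFrame
    total_productive_reads: int
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.clonotypes):
            if int(self.clonotypes["count"].sum()) != self.total_productive_reads:
                raise ValueError("clonotype counts do not sum to total_productive_reads")
            if abs(self.clonotypes["frequency"].sum() - 1.0) > 1e-9:
                raise ValueError("clonotype frequencies do not sum to 1")
            if (self.clonotypes["count"] < 1).any():
                raise ValueError("clonotype counts must be >= 1")

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    def cdr3_frequencies(self) -> np.ndarray:
        """Frequencies collapsed to unique CDR3aa (diversity-index scale)."""
        return self.clonotypes.groupby("cdr3_aa")["frequency"].sum().to_numpy()

    def unique_cdr3aa(self) -> set[str]:
        return set(self.clonotypes["cdr3_aa"])


class AnnotationEngine:
    """Precomputed, padded segment arrays for fast per-read annotation."""

    def __init__(self, ref: Reference, min_score: int = DEFAULT_MIN_SCORE):
        self.ref = ref
        self.min_score = min_score
        self._v = sorted(ref.v_segments, key=lambda s: s.id)
        self._j = sorted(ref.j_segments, key=lambda s: s.id)
        self._d = sorted(ref.d_segments, key=lambda s: s.id)
        self._v_mat, self._v_lens = _pad([s.seq_nt for s in self._v])
        self._j_mat, self._j_lens = _pad([s.seq_nt for s in self._j])

    def _best(self, read_codes: np.ndarray, segs, mat, lens) -> tuple[GermlineSegment, int] | None:
        scores = best_scores(read_codes, mat, lens)
        k = int(np.argmax(scores))  # segments are id-sorted: argmax takes first = lex smallest
        if scores[k] < self.min_score:
            return None
        return segs[k], int(scores[k])

    def assign_vj(self, read: SequenceRead) -> tuple[AlignmentHit, AlignmentHit] | None:
        """Best V hit and best J hit downstream of it, or None for a no-call."""
        codes = encode_nt(read.seq_nt)
        v_pick = self._best(codes, self._v, self._v_mat, self._v_lens)
        if v_pick is None:
            return None
        v_seg, _ = v_pick
        v_hit = align_segment(read.seq_nt, v_seg)
        suffix = read.seq_nt[v_hit.read_end :]
        if not suffix:
            return None
        j_pick = self._best(encode_nt(suffix), self._j, self._j_mat, self._j_lens)
        if j_pick is None:
            return None
        j_seg, _ = j_pick
        j_local = align_segment(suffix, j_seg)
        j_hit = AlignmentHit(
            j_local.segment_id,
            j_local.score,
            j_local.read_start + v_hit.read_end,
            j_local.read_end + v_hit.read_end,
            j_local.segment_start,
            j_local.segment_end,
        )
        return v_hit, j_hit

    def annotate(self, read: SequenceRead) -> Annotation | None:
        hits = self.assign_vj(read)
        if hits is None:
            return None
        v_hit, j_hit = hits
        cdr3_nt, cdr3_aa = extract_cdr3(read, v_hit, j_hit, self.ref)
        productive = is_productive(cdr3_nt) if cdr3_nt is not None else False
        d_call = assign_d(cdr3_nt, self._d) if cdr3_nt is not None else None
        return Annotation(
            read_id=read.id,
            v_call=v_hit.segment_id,
            j_call=j_hit.segment_id,
            d_call=d_call,
            cdr3_nt=cdr3_nt,
            cdr3_aa=cdr3_aa,
            productive=productive,
            v_score=v_hit.score,
            j_score=j_hit.score,
        )


def _pad(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    mat = np.zeros((len(seqs), int(lens.max())), dtype=np.int8)
    for i, s in enumerate(seqs):
        mat[i, : lens[i]] = encode_nt(s)
    return mat, lens


def assign_vj(
    read: SequenceRead, ref: Reference, min_score: int = DEFAULT_MIN_SCORE
) -> tuple[AlignmentHit, AlignmentHit] | None:
    """Convenience wrapper building a one-shot :class:`AnnotationEngine`."""
    return AnnotationEngine(ref, min_score).assign_vj(read)


def extract_cdr3(
    read: SequenceRead, v_hit: AlignmentHit, j_hit: AlignmentHit, ref: Reference
) -> tuple[str | None, str | None]:
    """Anchor-inclusive CDR3: V-Cys codon start through J-Phe codon end.

    Returns (None, None) when either anchor codon is not covered by its
    alignment or maps to a gap (the annotation is then non-productive).
    """
    v_seg = ref[v_hit.segment_id]
    j_seg = ref[j_hit.segment_id]
    va, ja = v_seg.anchor_nt, j_seg.anchor_nt
    if not (v_hit.segment_start <= va < v_hit.segment_end):
        return None, None
    if not (j_hit.segment_start <= ja and ja + 2 < j_hit.segment_end):
        return None, None
    start = alignment_read_position(read.seq_nt, v_seg, v_hit, va)
    # J alignment coordinates were computed on the read suffix; shift back.
    j_local = AlignmentHit(
        j_hit.segment_id,
        j_hit.score,
        0,
        j_hit.read_end - j_hit.read_start,
        j_hit.segment_start,
        j_hit.segment_end,
    )
    suffix = read.seq_nt[j_hit.read_start : j_hit.read_end]
    end_local = alignment_read_position(suffix, j_seg, j_local, ja + 2)
    if start < 0 or end_local < 0:
        return None, None
    end = end_local + j_hit.read_start + 1
    cdr3_nt = read.seq_nt[start:end]
    cdr3_aa = translate_nt(cdr3_nt) if len(cdr3_nt) % 3 == 0 and "N" not in cdr3_nt else None
    return cdr3_nt, cdr3_aa


def assign_d(cdr3_nt: str, d_segments: Iterable[GermlineSegment], min_len: int = 5) -> str | None:
    """D call by longest exact substring match (>= min_len) inside the junction.

    Ties between D segments (equal longest match) give no call.
    """
    best_len, best_ids = 0, []
    for seg in d_segments:
        longest = 0
        dseq = seg.seq_nt
        for length in range(len(dseq), min_len - 1, -1):
            found = False
            for off in range(0, len(dseq) - length + 1):
                if dseq[off : off + length] in cdr3_nt:
                    found = True
                    break
            if found:
                longest = length
                break
        if longest > best_len:
            best_len, best_ids = longest, [seg.id]
        elif longest == best_len and longest > 0:
            best_ids.append(seg.id)
    if best_len >= min_len and len(best_ids) == 1:
        return best_ids[0]
    return None


def is_productive(cdr3_nt: str) -> bool:
    """In-frame, stop-free junction with intact C...F anchors."""
    if len(cdr3_nt) % 3 != 0 or len(cdr3_nt) == 0:
        return False
    if any(b not in "ACGT" for b in cdr3_nt):
        return False
    aa = translate_nt(cdr3_nt)
    return aa.startswith("C") and aa.endswith("F") and "*" not in aa


def annotate_reads(
    reads: Iterable[SequenceRead], ref: Reference, min_score: int = DEFAULT_MIN_SCORE
) -> tuple[list[Annotation], int]:
    """Annotate a read stream; returns (annotations, n_no_call)."""
    engine = AnnotationEngine(ref, min_score)
    annotations, no_call = [], 0
    for read in reads:
        ann = engine.annotate(read)
        if ann is None:
            no_call += 1
        else:
            annotations.append(ann)
    return annotations, no_call


def build_repertoire(
    annotations: Iterable[Annotation],
    sample_id: str,
    group: str | None = None,
    clinical: dict[str, float] | None = None,
) -> Repertoire:
    """Group productive annotations into a clonotype table.

    Clonotype key is (cdr3_aa, v_call, j_call); the ``d_call`` column holds
    the most frequent non-null D call among the clonotype's reads (ties to
    the lexicographically smallest), or null.  Frequencies are counts over
    total productive reads.  Zero productive annotations give an empty
    repertoire.
    """
    rows = [
        (a.cdr3_aa, a.v_call, a.j_call, a.d_call)
        for a in annotations
        if a.productive and a.cdr3_aa is not None
    ]
    if not rows:
        empty = pd.DataFrame(
            columns=["cdr3_aa", "v_call", "d_call", "j_call", "count", "frequency"]
        )
        return Repertoire(sample_id, group, empty, 0, clinical or {})
    df = pd.DataFrame(rows, columns=["cdr3_aa", "v_call", "j_call", "d_call"])

    def _majority_d(values: pd.Series) -> str | None:
        non_null = values.dropna()
        if non_null.empty:
            return None
        counts = non_null.value_counts()
        top = counts[counts == counts.max()]
        return sorted(top.index)[0]

    grouped = (
        df.groupby(["cdr3_aa", "v_call", "j_call"], sort=True)
        .agg(count=("d_call", "size"), d_call=("d_call", _majority_d))
        .reset_index()
    )
    total = int(grouped["count"].sum())
    grouped["frequency"] = grouped["count"] / total
    grouped = grouped[["cdr3_aa", "v_call", "d_call", "j_call", "count", "frequency"]]
    return Repertoire(sample_id, group, grouped, total, clinical or {})
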