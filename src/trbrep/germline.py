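"""Germline V/D/J segment reference for the TCR-beta locus.

A :class:`Reference` holds the segment space the annotator aligns against:
V segments carry the position of the conserved second cysteine codon, J
segments the position of the conserved phenylalanine codon; the CDR3
junction is the read span between (and including) those two anchor codons.
Gene names follow IMGT style (``TRBV7-6`` = family TRBV7, subfamily 6), and
family-level collapsing sums usage over subfamilies.

The bundled reference (``data/trb_synthetic_reference.fasta`` plus anchor
table) is *synthetic*: 58 V, 2 D and 14 J segments with realistic names
spanning 28 V families, generated once from a fixed seed.  Segment
sequences are random nucleotides with correct anchor codons - sufficient
for amplicon CDR3 work, where only the anchors and segment identity
matter, and it keeps the package free of licensed germline downloads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "SegmentKind",
    "GermlineSegment",
    "Reference",
    "load_reference",
    "load_bundled_reference",
    "family_of",
    "collapse_families",
    "build_synthetic_reference",
]

GENETIC_CODE = {}  # codon (str) -> amino acid, '*' for stop; filled below


def _build_genetic_code() -> None:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    GENETIC_CODE.update(table.forward_table)
    for codon in table.stop_codons:
        GENETIC_CODE[codon] = "*"


_build_genetic_code()


def translate_nt(nt: str) -> str:
    """Translate a nucleotide string (length divisible by 3), stops as '*'."""
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} not divisible by 3")
    return "".join(GENETIC_CODE[nt[i : i + 3]] for i in range(0, len(nt), 3))


class SegmentKind(str, Enum):
    V = "V"
    D = "D"
    J = "J"


@dataclass(frozen=True)
class GermlineSegment:
    """One germline segment: sequence plus conserved-anchor coordinate.

    ``anchor_nt`` is the 0-based offset of the first base of the conserved
    anchor codon (Cys for V, Phe for J); ``None`` for D segments.  All
    intervals in this package are half-open ``[start, end)``.
    """

    id: str
    kind: SegmentKind
    seq_nt: str
    anchor_nt: int | None = None

    @property
    def family(self) -> str:
        return family_of(self.id)

    def __post_init__(self) -> None:
        if self.kind in (SegmentKind.V, SegmentKind.J):
            if self.anchor_nt is None:
                raise ValueError(f"{self.id}: {self.kind.value} segment needs an anchor")
            if self.anchor_nt + 3 > len(self.seq_nt):
                raise ValueError(f"{self.id}: anchor codon extends past sequence end")
            codon = self.seq_nt[self.anchor_nt : self.anchor_nt + 3]
            aa = GENETIC_CODE.get(codon)
            want = "C" if self.kind is SegmentKind.V else "F"
            if aa != want:
                raise ValueError(
                    f"{self.id}: anchor codon {codon} translates to {aa}, expected {want}"
                )


@dataclass
class Reference:
    """A validated set of germline segments with unique ids."""

    segments: list[GermlineSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate segment ids: {dup}")
        if not self.by_kind(SegmentKind.V) or not self.by_kind(SegmentKind.J):
            raise ValueError("reference must contain at least one V and one J segment")

    def by_kind(self, kind: SegmentKind) -> list[GermlineSegment]:
        return [s for s in self.segments if s.kind is kind]

    @property
    def v_segments(self) -> list[GermlineSegment]:
        return self.by_kind(SegmentKind.V)

    @property
    def d_segments(self) -> list[GermlineSegment]:
        return self.by_kind(SegmentKind.D)

    @property
    def j_segments(self) -> list[GermlineSegment]:
        return self.by_kind(SegmentKind.J)

    @property
    def v_ids(self) -> list[str]:
        return [s.id for s in self.v_segments]

    @property
    def j_ids(self) -> list[str]:
        return [s.id for s in self.j_segments]

    def __getitem__(self, seg_id: str) -> GermlineSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    def counts(self) -> dict[str, int]:
        return {k.value: len(self.by_kind(k)) for k in SegmentKind}


_ID_RE = re.compile(r"^(TR[AB][VDJ])(\d+)(?:-(\w+))?$")


def family_of(segment_id: str) -> str:
    """Family name of an IMGT-style segment id.

    Truncates before the first ``-`` following the family number:
    ``TRBV7-6`` -> ``TRBV7``; ids without a subfamily token (``TRBV16``)
    are their own family. Idempotent: a family name maps to itself.
    Pseudogene-style suffixes (``TRBJ2-2p``) are part of the subfamily
    token and drop with it.
    """
    m = _ID_RE.match(segment_id)
    if m is None:
        raise ValueError(f"unparseable segment id: {segment_id!r}")
    return m.group(1) + m.group(2)


def collapse_families(usage: dict[str, float]) -> dict[str, float]:
    """Sum a per-segment frequency map into a per-family map (total conserved)."""
    out: dict[str, float] = {}
    for seg_id, value in usage.items():
        if value < 0:
            raise ValueError(f"negative usage for {seg_id}")
        fam = family_of(seg_id)
        out[fam] = out.get(fam, 0.0) + value
    return out


def load_reference(fasta_path: str | Path, anchor_table_path: str | Path) -> Reference:
    """Load a reference from a multi-FASTA plus a tab-separated anchor table.

    The anchor table has columns ``id``, ``kind``, ``anchor_nt`` (anchor_nt
    empty or ``NA`` for D segments).  Every FASTA V/J id must appear in the
    table; anchor codons are validated against the genetic code on load.
    """
    from Bio import SeqIO

    meta: dict[str, tuple[SegmentKind, int | None]] = {}
    with open(anchor_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        want = ["id", "kind", "anchor_nt"]
        if header != want:
            raise ValueError(f"anchor table header {header} != {want}")
        for line in fh:
            if not line.strip():
                continue
            seg_id, kind, anchor = line.rstrip("\n").split("\t")
            meta[seg_id] = (
                SegmentKind(kind),
                None if anchor in ("", "NA") else int(anchor),
            )

    segments = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta:
            raise ValueError(f"segment {rec.id} in FASTA but missing from anchor table")
        kind, anchor = meta[rec.id]
        segments.append(GermlineSegment(rec.id, kind, str(rec.seq).upper(), anchor))
    loaded = {s.id for s in segments}
    missing = sorted(set(meta) - loaded)
    if missing:
        raise ValueError(f"anchor table ids missing from FASTA: {missing}")
    return Reference(segments)


def load_bundled_reference() -> Reference:
    """Load the bundled synthetic 58 V / 2 D / 14 J reference."""
    data = resources.files("trbrep") / "data"
    return load_reference(
        Path(str(data / "trb_synthetic_reference.fasta")),
        Path(str(data / "trb_synthetic_anchors.tsv")),
    )


# --- synthetic reference construction -------------------------------------

# 58 V subfamilies in 28 families (TRBV7 contributes 8, incl. TRBV7-6),
# 14 J subfamilies in 2 families (TRBJ2-2p kept as an ordinary segment).
_V_IDS = (
    ["TRBV1", "TRBV2"]
    + ["TRBV3-1", "TRBV3-2"]
    + [f"TRBV4-{i}" for i in (1, 2, 3)]
    + [f"TRBV5-{i}" for i in (1, 3, 4, 5, 6, 7, 8)]
    + [f"TRBV6-{i}" for i in range(1, 9)]
    + [f"TRBV7-{i}" for i in (1, 2, 3, 4, 6, 7, 8, 9)]
    + ["TRBV9"]
    + [f"TRBV10-{i}" for i in (1, 2, 3)]
    + [f"TRBV11-{i}" for i in (1, 2, 3)]
    + [f"TRBV12-{i}" for i in (1, 2, 3, 4)]
    + ["TRBV13", "TRBV14", "TRBV15", "TRBV16", "TRBV17", "TRBV18", "TRBV19"]
    + ["TRBV20-1", "TRBV21-1", "TRBV23-1", "TRBV24-1", "TRBV25-1"]
    + ["TRBV26", "TRBV27", "TRBV28", "TRBV29-1", "TRBV30"]
)
_J_IDS = [f"TRBJ1-{i}" for i in range(1, 7)] + [f"TRBJ2-{i}" for i in range(1, 8)] + [
    "TRBJ2-2p"
]
_D_SEQS = {"TRBD1": "GGGACAGGGGGC", "TRBD2": "GGGACTAGCGGGGGGG"}

_V_LEN, _V_ANCHOR = 63, 54  # Cys codon at 54..57, 6 germline nt beyond it
_J_LEN, _J_ANCHOR = 48, 9  # 9 germline nt precede the Phe codon


def build_synthetic_reference(seed: int = 20240827) -> Reference:
    """Deterministically construct the synthetic reference (see module docstring)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand_nt(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    segments = []
    for vid in _V_IDS:
        seq = rand_nt(_V_ANCHOR) + ("TGT" if rng.random() < 0.5 else "TGC") + rand_nt(
            _V_LEN - _V_ANCHOR - 3
        )
        segments.append(GermlineSegment(vid, SegmentKind.V, seq, _V_ANCHOR))
    for did, dseq in _D_SEQS.items():
        segments.append(GermlineSegment(did, SegmentKind.D, dseq, None))
    for jid in _J_IDS:
        seq = rand_nt(_J_ANCHOR) + ("TTT" if rng.random() < 0.5 else "TTC") + rand_nt(
            _J_LEN - _J_ANCHOR - 3
        )
        segments.append(GermlineSegment(jid, SegmentKind.J, seq, _J_ANCHOR))
    return Reference(segments)


def write_reference(ref: Reference, fasta_path: str | Path, anchor_table_path: str | Path) -> None:
    """Write a reference in the bundled two-file format."""
    with open(fasta_path, "w") as fa:
        for s in ref.segments:
            fa.write(f">{s.id}\n{s.seq_nt}\n")
    with open(anchor_table_path, "w") as tsv:
        tsv.write("id\tkind\tanchor_nt\n")
        for s in ref.segments:
            anchor = "NA" if s.anchor_nt is None else str(s.anchor_nt)
            tsv.write(f"{s.id}\t{s.kind.value}\t{anchor}\n")
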