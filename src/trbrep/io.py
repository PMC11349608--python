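"""FASTQ input, read quality control, and AIRR-style clonotype TSV round-trip.

QC mirrors the amplicon-repertoire convention: a read is discarded when it
carries more than ``max_ambiguous`` N bases, or when at least
``max_low_q_fraction`` of its positions fall below ``phred_min``.  The
low-quality threshold is inclusive (a 100-nt read with exactly 15
positions under Q30 is removed at the defaults); a read failing both
filters is attributed to the ambiguous-base counter, which is checked
first.  Only Phred+33 FASTQ is supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SequenceRead",
    "QcParams",
    "QcReport",
    "read_fastq",
    "qc_filter",
    "write_airr",
    "read_airr",
    "AIRR_COLUMNS",
]

PHRED_OFFSET = 33

#: Mandatory columns of the AIRR-style Rearrangement TSV this package emits.
AIRR_COLUMNS = [
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "duplicate_count",
    "frequency",
]


@dataclass(frozen=True)
class SequenceRead:
    """One amplicon read with per-base Phred qualities."""

    id: str
    seq_nt: str
    quals: np.ndarray  # int array, same length as seq_nt

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq_nt):
            raise ValueError(
                f"read {self.id}: {len(self.seq_nt)} bases but {len(self.quals)} qualities"
            )


@dataclass(frozen=True)
class QcParams:
    max_ambiguous: int = 8
    phred_min: int = 30
    max_low_q_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.max_ambiguous < 0:
            raise ValueError("max_ambiguous must be >= 0")
        if not 0.0 <= self.max_low_q_fraction <= 1.0:
            raise ValueError("max_low_q_fraction must be in [0, 1]")


@dataclass
class QcReport:
    n_raw: int = 0
    n_kept: int = 0
    n_removed_ambiguous: int = 0
    n_removed_quality: int = 0

    def check(self) -> None:
        assert self.n_kept + self.n_removed_ambiguous + self.n_removed_quality == self.n_raw


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Yield reads from a Phred+33 FASTQ file in file order.

    Malformed records (sequence/quality length mismatch, truncated file)
    raise ``ValueError`` naming the record index.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {index}: sequence length {len(seq)} "
                    f"!= quality length {len(qual)}"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
            quals -= PHRED_OFFSET
            if quals.size and quals.min() < 0:
                raise ValueError(f"malformed FASTQ record {index}: quality below Phred+33 range")
            yield SequenceRead(title.split()[0], seq.upper(), quals)
            index += 1


def qc_filter(
    reads: Iterable[SequenceRead], params: QcParams = QcParams()
) -> tuple[list[SequenceRead], QcReport]:
    """Apply the ambiguous-base and low-quality filters; order-preserving.

    Removal rule: (count of N > max_ambiguous) OR
    (fraction of positions with Phred < phred_min >= max_low_q_fraction).
    """
    report = QcReport()
    kept: list[SequenceRead] = []
    for read in reads:
        report.n_raw += 1
        if read.seq_nt.count("N") > params.max_ambiguous:
            report.n_removed_ambiguous += 1
            continue
        n = len(read.seq_nt)
        if n and (np.count_nonzero(read.quals < params.phred_min) / n) >= params.max_low_q_fraction:
            report.n_removed_quality += 1
            continue
        report.n_kept += 1
        kept.append(read)
    report.check()
    return kept, report


def _to_airr_frame(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    missing = [c for c in AIRR_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"missing mandatory AIRR columns: {missing}")
    out = out[AIRR_COLUMNS]
    out["productive"] = out["productive"].map(lambda b: "T" if b else "F")
    out["d_call"] = out["d_call"].fillna("")
    return out


def write_airr(table: pd.DataFrame, path: str | Path) -> None:
    """Write a clonotype/annotation table as AIRR-style Rearrangement TSV."""
    _to_airr_frame(table).to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    """Read an AIRR-style TSV back into a typed DataFrame (round-trip identity)."""
    table = pd.read_csv(
        path, sep="\t", dtype={"sequence_id": str, "d_call": str}, keep_default_na=False
    )
    missing = [c for c in AIRR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing mandatory AIRR columns: {missing}")
    table["productive"] = table["productive"].map({"T": True, "F": False})
    if table["productive"].isna().any():
        raise ValueError("productive column must contain only 'T'/'F'")
    table["duplicate_count"] = table["duplicate_count"].astype(int)
    table["frequency"] = table["frequency"].astype(float)
    return table
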