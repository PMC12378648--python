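"""Apply a truncation plan to read streams with DADA2-compatible semantics.

A read is discarded if it is shorter than the truncation length;
otherwise it is cut to exactly ``trunc_len`` cycles and then the first
``trim_left`` bases (primer/adapter remnants) are removed.  Truncation
happens in raw-read coordinates, so ``trunc_len`` refers to the same
cycle index the quality profile indexed; every surviving read has length
``trunc_len - trim_left``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Union
from pathlib import Path

from .fastq_io import ReadRecord, read_fastq, write_fastq

DEFAULT_TRIM_LEFT = 5


@dataclass(frozen=True)
class TrimSpec:
    """Truncation length and left-trim, both in raw-read coordinates."""

    trunc_len: int
    trim_left: int = DEFAULT_TRIM_LEFT

    def __post_init__(self) -> None:
        if self.trunc_len < 1:
            raise ValueError("trunc_len must be >= 1")
        if not 0 <= self.trim_left < self.trunc_len:
            raise ValueError("require 0 <= trim_left < trunc_len")

    @property
    def output_len(self) -> int:
        return self.trunc_len - self.trim_left


@dataclass
class TrimStats:
    """Counts accumulated while a trim stream is consumed."""

    kept: int = 0
    discarded: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.discarded


def truncate_and_trim(
    records: Iterable[ReadRecord],
    spec: TrimSpec,
    stats: Optional[TrimStats] = None,
) -> Iterator[ReadRecord]:
    """Yield trimmed records; update ``stats`` as the stream is consumed.

    Reads shorter than ``spec.trunc_len`` are dropped and counted in
    ``stats.discarded``; reads exactly ``trunc_len`` long are kept.
    """
    if stats is None:
        stats = TrimStats()
    for rec in records:
        if len(rec) < spec.trunc_len:
            stats.discarded += 1
            continue
        stats.kept += 1
        yield ReadRecord(
            rec.read_id,
            rec.bases[spec.trim_left : spec.trunc_len],
            rec.quals[spec.trim_left : spec.trunc_len],
        )


def trim_fastq(
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    spec: TrimSpec,
    encoding: str = "auto",
) -> TrimStats:
    """Trim one FASTQ file to another; return kept/discarded counts."""
    stats = TrimStats()
    write_fastq(
        truncate_and_trim(read_fastq(in_path, encoding), spec, stats),
        out_path,
    )
    return stats
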