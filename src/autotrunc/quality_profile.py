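"""Per-position quality statistics for one FASTQ file.

This is the in-house quality-control stage the truncation-point detector
runs on: for every read position (sequencing cycle) it computes coverage,
mean and exact median PHRED score, plus the file-level grand-mean quality
over all base calls.  Unlike FastQC the statistics are exact — no quality
binning — which matters because the truncation rule compares a per-cycle
median against the file average with a strict inequality.

Internally a streaming histogram of 94 PHRED bins per position is kept,
so memory is O(read_length * 94) regardless of file size and medians are
exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

from .fastq_io import MAX_PHRED, ReadRecord

#: Positions reached by fewer than this fraction of reads are excluded
#: from the profile (straggler-read tails give meaningless medians).
MIN_COVERAGE_FRACTION = 0.01

_N_BINS = MAX_PHRED + 1


@dataclass
class QualityProfile:
    """Quality summary of one FASTQ file.

    Positions are sequencing cycles, 1-based in reports; the arrays here
    are 0-based, so ``pos_median[p - 1]`` is the median of cycle ``p``.
    Only positions covered by at least 1% of reads are profiled; with
    fixed-length Illumina reads that is every position.

    ``grand_mean`` is the mean PHRED over *all* base calls in the file
    (including any excluded low-coverage tail) — the "average quality"
    the truncation rule compares per-cycle medians against.
    """

    n_reads: int
    max_len: int
    coverage: np.ndarray
    pos_mean: np.ndarray
    pos_median: np.ndarray
    grand_mean: float
    source: str = ""

    @property
    def n_positions(self) -> int:
        """Number of profiled positions (after low-coverage exclusion)."""
        return int(self.coverage.size)


def profile_fastq(
    records: Iterable[ReadRecord], source: str = ""
) -> QualityProfile:
    """Stream records once and return their :class:`QualityProfile`.

    Raises ``ValueError`` on an empty stream or if every read is empty.
    """
    counts = np.zeros((0, _N_BINS), dtype=np.int64)
    n_reads = 0
    for rec in records:
        n_reads += 1
        length = len(rec)
        if length > counts.shape[0]:
            counts = np.vstack(
                [counts, np.zeros((length - counts.shape[0], _N_BINS), np.int64)]
            )
        if length:
            np.add.at(counts, (np.arange(length), rec.quals), 1)
    if n_reads == 0:
        raise ValueError(f"no reads in {source or 'input'}")
    if counts.shape[0] == 0:
        raise ValueError(f"all reads in {source or 'input'} are empty")

    coverage_full = counts.sum(axis=1)
    scores = np.arange(_N_BINS, dtype=np.int64)
    total_calls = int(coverage_full.sum())
    grand_mean = float((counts @ scores).sum() / total_calls)

    # coverage is non-increasing, so the kept positions form a prefix
    keep = coverage_full >= MIN_COVERAGE_FRACTION * n_reads
    n_pos = int(keep.sum())
    counts = counts[:n_pos]
    coverage = coverage_full[:n_pos]

    pos_mean = (counts @ scores) / coverage
    cum = counts.cumsum(axis=1)
    lo_rank = (coverage - 1) // 2  # 0-based ranks of the central value(s)
    hi_rank = coverage // 2
    lo = (cum <= lo_rank[:, None]).sum(axis=1)
    hi = (cum <= hi_rank[:, None]).sum(axis=1)
    pos_median = (lo + hi) / 2.0

    return QualityProfile(
        n_reads=n_reads,
        max_len=int(coverage_full.size),
        coverage=coverage,
        pos_mean=pos_mean,
        pos_median=pos_median,
        grand_mean=grand_mean,
        source=source,
    )


def write_profile_tsv(
    profile: QualityProfile, dest: Union[str, Path, IO[str]]
) -> None:
    """Export a profile as TSV: position, coverage, mean, median."""

    def _emit(fh: IO[str]) -> None:
        fh.write("position\tcoverage\tmean\tmedian\n")
        for i in range(profile.n_positions):
            fh.write(
                f"{i + 1}\t{int(profile.coverage[i])}\t"
                f"{profile.pos_mean[i]:.4f}\t{profile.pos_median[i]:g}\n"
            )

    if hasattr(dest, "write"):
        _emit(dest)  # type: ignore[arg-type]
    else:
        with open(dest, "w", encoding="ascii") as fh:
            _emit(fh)


def tail_mean_quality(profile: QualityProfile, tail_fraction: float = 0.2) -> float:
    """Mean of the per-position means over the last ``tail_fraction`` of
    profiled positions (used to judge reverse-read tail quality)."""
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    n_tail = max(1, math.ceil(tail_fraction * profile.n_positions))
    return float(profile.pos_mean[-n_tail:].mean())
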