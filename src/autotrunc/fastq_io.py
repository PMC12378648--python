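"""Streaming FASTQ input/output with PHRED-encoding handling.

Reads the 4-line Illumina FASTQ dialect, plain or gzip-compressed
(compression is recognised by the file's magic bytes, not its name).
Quality strings are decoded to integer PHRED scores; the encoding offset
(phred33 vs. the legacy phred64) can be detected automatically from the
observed quality characters.  Writing always emits phred33, the encoding
of every current Illumina instrument.

These functions are generators/consumers of :class:`ReadRecord` streams,
so memory use is independent of file size.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import numpy as np

logger = logging.getLogger(__name__)

PHRED33_OFFSET = 33
PHRED64_OFFSET = 64
#: Highest PHRED score representable in phred33 with printable ASCII ('~').
MAX_PHRED = 93
#: How many quality characters the auto-detector inspects at most.
_DETECT_LIMIT = 10_000

GZIP_MAGIC = b"\x1f\x8b"

PathLike = Union[str, Path]


class FastqParseError(ValueError):
    """Structurally malformed FASTQ (bad 4-line block)."""


class FastqEncodingError(ValueError):
    """Quality characters incompatible with the requested/known encodings."""


@dataclass
class ReadRecord:
    """One sequencing read: identifier, bases and integer PHRED scores.

    ``quals`` is a uint8 array the same length as ``bases``; every score
    lies in ``[0, 93]`` (enforced on construction).
    """

    read_id: str
    bases: str
    quals: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.bases) != self.quals.size:
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{self.quals.size} quality scores"
            )
        if self.quals.size and int(self.quals.max()) > MAX_PHRED:
            raise ValueError(
                f"read {self.read_id!r}: PHRED score above {MAX_PHRED}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadRecord):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and self.bases == other.bases
            and np.array_equal(self.quals, other.quals)
        )


def _is_gzip(path: PathLike) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def _open_text(path: PathLike) -> IO[str]:
    if _is_gzip(path):
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, "rt", encoding="ascii")


def detect_encoding(path: PathLike) -> str:
    """Infer the PHRED offset of a FASTQ file from its quality characters.

    Scans up to the first 10,000 quality characters.  Any character below
    ASCII 64 can only be phred33; a range confined to [64, 74] is formally
    ambiguous and resolved to phred33 (the modern default) with a logged
    warning; otherwise phred64 is assumed.
    """
    lo, hi = 0x7F, 0
    seen = 0
    with _open_text(path) as fh:
        while seen < _DETECT_LIMIT:
            block = [fh.readline() for _ in range(4)]
            if not block[0]:
                break
            qual = block[3].rstrip("\n")
            if not qual:
                continue
            arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
            lo = min(lo, int(arr.min()))
            hi = max(hi, int(arr.max()))
            seen += arr.size
    if seen == 0:
        return "phred33"
    if lo < PHRED33_OFFSET or hi > 126:
        raise FastqEncodingError(
            f"{path}: quality characters outside both PHRED encodings "
            f"(ASCII range {lo}..{hi})"
        )
    if lo < PHRED64_OFFSET:
        return "phred33"
    if hi <= 74:
        logger.warning(
            "%s: quality characters all in ASCII [64, 74]; encoding is "
            "ambiguous, defaulting to phred33",
            path,
        )
        return "phred33"
    return "phred64"


def read_fastq(
    path: PathLike, encoding: str = "auto"
) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` objects from a FASTQ file, in file order.

    Parameters
    ----------
    path
        FASTQ file, optionally gzip-compressed (detected by magic bytes).
    encoding
        ``"phred33"``, ``"phred64"`` or ``"auto"`` (infer from the data).

    Raises
    ------
    FastqParseError
        On a malformed 4-line block, naming the offending line number.
    FastqEncodingError
        On quality characters invalid under the resolved encoding.
    """
    if encoding == "auto":
        encoding = detect_encoding(path)
    if encoding not in ("phred33", "phred64"):
        raise ValueError(f"unknown encoding {encoding!r}")
    offset = PHRED33_OFFSET if encoding == "phred33" else PHRED64_OFFSET

    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            head_line = lineno
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}: line {head_line}: expected '@' header, "
                    f"got {header.rstrip()[:30]!r}"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if seq == "" or plus == "" or qual == "":  # EOF mid-record
                raise FastqParseError(
                    f"{path}: truncated record starting at line {head_line}"
                )
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: line {head_line + 2}: expected '+' separator"
                )
            bases = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if len(bases) != len(qual):
                raise FastqParseError(
                    f"{path}: line {head_line + 3}: quality length "
                    f"{len(qual)} != sequence length {len(bases)}"
                )
            raw = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
            quals = raw.astype(np.int16) - offset
            if quals.size and (quals.min() < 0 or quals.max() > MAX_PHRED):
                raise FastqEncodingError(
                    f"{path}: line {head_line + 3}: quality character "
                    f"outside {encoding} range"
                )
            yield ReadRecord(header[1:].rstrip("\n"), bases, quals)


def write_fastq(records: Iterable[ReadRecord], path: PathLike) -> int:
    """Write records to ``path`` as phred33 FASTQ; return the record count.

    Gzip compression is applied when the output name ends in ``.gz``.
    ``read_fastq(write_fastq(X))`` reproduces ``X`` exactly.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt", encoding="ascii") as fh:
        for rec in records:
            qual = (rec.quals.astype(np.uint8) + PHRED33_OFFSET).tobytes()
            fh.write(
                f"@{rec.read_id}\n{rec.bases}\n+\n{qual.decode('ascii')}\n"
            )
            n += 1
    return n
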