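"""Truncation-length selection with a paired-end overlap constraint.

The algorithm, per run direction:

1. For each FASTQ file, find the first sequencing cycle whose median
   PHRED score drops strictly below the file's grand-mean quality; the
   file's truncation point keeps the cycles strictly before it.
2. Average the per-file truncation points within each direction
   (floor-rounded) to get the raw forward/reverse truncation lengths.
3. If the expected merge overlap ``r1 + r2 - amplicon_len`` falls below
   the required minimum (12 nt for DADA2 merging), lengthen the forward
   truncation only — forward cycles are the higher-quality ones — up to
   the physical read length.  The reverse truncation is never changed.

The resulting plan carries the two lengths conventionally exported as
the shell variables ``R1TRUN`` and ``R2TRUN`` for a DADA2/QIIME 2
command line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quality_profile import QualityProfile, tail_mean_quality

FORWARD = "forward"
REVERSE = "reverse"

#: Minimum forward/reverse overlap DADA2 needs to merge a pair.
DEFAULT_MIN_OVERLAP = 12
#: MiSeq 2x300 cycle count, the physical cap on any truncation length.
DEFAULT_MAX_READ_LEN = 300
#: Reverse-tail mean quality below which single-end analysis is advised.
DEFAULT_TAIL_QUALITY_FLOOR = 20
DEFAULT_TAIL_FRACTION = 0.2


class TruncationError(ValueError):
    """The crossing rule yields no usable truncation length."""


@dataclass(frozen=True)
class TruncationPoint:
    """Per-file truncation length (cycles to keep)."""

    source: str
    direction: str
    length: int

    def __post_init__(self) -> None:
        if self.direction not in (FORWARD, REVERSE):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.length < 1:
            raise ValueError("truncation length must be >= 1")


@dataclass(frozen=True)
class AmpliconModel:
    """Merge-overlap geometry of the sequenced amplicon.

    ``amplicon_len`` is the expected template length in nt (primer to
    primer as sequenced); ``min_overlap`` the minimum forward/reverse
    overlap required for merging; ``max_read_len`` the cycle count of
    the sequencing run.
    """

    amplicon_len: int
    min_overlap: int = DEFAULT_MIN_OVERLAP
    max_read_len: int = DEFAULT_MAX_READ_LEN

    def __post_init__(self) -> None:
        if self.amplicon_len <= 0:
            raise ValueError("amplicon_len must be positive")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_overlap >= 2 * self.max_read_len:
            raise ValueError("min_overlap must be < 2 * max_read_len")


@dataclass(frozen=True)
class TruncationPlan:
    """Raw and overlap-constrained truncation lengths for both directions.

    ``r1_final``/``r2_final`` are the values exported as R1TRUN/R2TRUN.
    ``constrained`` is true iff the overlap constraint moved r1;
    ``feasible`` is true iff the final plan reaches ``min_overlap``.
    The reverse length is never adjusted (``r2_final == r2_raw``).
    """

    r1_raw: int
    r2_raw: int
    r1_final: int
    r2_final: int
    constrained: bool
    feasible: bool
    model: AmpliconModel

    @property
    def expected_overlap(self) -> int:
        return self.r1_final + self.r2_final - self.model.amplicon_len

    def to_dict(self) -> dict:
        return {
            "r1_raw": self.r1_raw,
            "r2_raw": self.r2_raw,
            "r1_final": self.r1_final,
            "r2_final": self.r2_final,
            "constrained": self.constrained,
            "feasible": self.feasible,
            "expected_overlap": self.expected_overlap,
            "amplicon_len": self.model.amplicon_len,
            "min_overlap": self.model.min_overlap,
            "max_read_len": self.model.max_read_len,
        }


@dataclass(frozen=True)
class StrategyRecommendation:
    strategy: str  # "paired" | "single_forward"
    rationale: str


def find_truncation_point(
    profile: QualityProfile, direction: str = FORWARD
) -> TruncationPoint:
    """Apply the crossing rule to one file's quality profile.

    The truncation point is ``p* - 1`` where ``p*`` is the first position
    whose median PHRED is strictly below the file's grand-mean quality;
    if the median never drops below the average, the whole profiled
    length is kept.

    Raises :class:`TruncationError` when the crossing happens at the
    very first position (length 0 is meaningless; truncate manually).
    """
    below = np.nonzero(profile.pos_median < profile.grand_mean)[0]
    if below.size == 0:
        length = profile.n_positions
    else:
        crossing = int(below[0]) + 1  # 1-based position of first drop
        if crossing == 1:
            raise TruncationError(
                f"{profile.source or 'input'}: median quality is below the "
                "file average already at position 1; choose a truncation "
                "length manually"
            )
        length = crossing - 1
    return TruncationPoint(profile.source, direction, length)


def aggregate_truncation(
    points: Sequence[TruncationPoint], direction: str
) -> int:
    """Floor of the mean truncation length over files of one direction."""
    lengths = [p.length for p in points if p.direction == direction]
    if not lengths:
        raise ValueError(f"no truncation points for direction {direction!r}")
    return math.floor(sum(lengths) / len(lengths))


def apply_overlap_constraint(
    r1_raw: int, r2_raw: int, model: AmpliconModel
) -> TruncationPlan:
    """Enforce the minimum merge overlap by lengthening r1 only.

    Expected overlap is ``r1 + r2 - amplicon_len``.  When it already
    meets ``min_overlap`` the plan is unconstrained.  Otherwise r1 is
    raised to the smallest length restoring the overlap, capped at the
    physical read length; if the cap still leaves the overlap short the
    plan is flagged infeasible (a reported state, not an error).
    """
    if not 1 <= r1_raw <= model.max_read_len:
        raise ValueError("r1_raw outside [1, max_read_len]")
    if not 1 <= r2_raw <= model.max_read_len:
        raise ValueError("r2_raw outside [1, max_read_len]")

    overlap = r1_raw + r2_raw - model.amplicon_len
    if overlap >= model.min_overlap:
        r1_final = r1_raw
    else:
        required = model.amplicon_len + model.min_overlap - r2_raw
        r1_final = min(required, model.max_read_len)
    feasible = r1_final + r2_raw - model.amplicon_len >= model.min_overlap
    return TruncationPlan(
        r1_raw=r1_raw,
        r2_raw=r2_raw,
        r1_final=r1_final,
        r2_final=r2_raw,
        constrained=r1_final != r1_raw,
        feasible=feasible,
        model=model,
    )


def recommend_strategy(
    plan: TruncationPlan,
    reverse_profile: QualityProfile,
    tail_quality_floor: float = DEFAULT_TAIL_QUALITY_FLOOR,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
) -> StrategyRecommendation:
    """Advise paired-end vs. forward-only denoising.

    Forward-only is recommended when the overlap constraint cannot be
    satisfied, or when the mean quality over the last ``tail_fraction``
    of reverse positions falls below ``tail_quality_floor`` — reverse
    tails that poor tend to defeat merging even when the geometry works.
    """
    if not plan.feasible:
        return StrategyRecommendation(
            "single_forward",
            "overlap infeasible: "
            f"max achievable overlap {plan.expected_overlap} nt < "
            f"required {plan.model.min_overlap} nt",
        )
    tail_q = tail_mean_quality(reverse_profile, tail_fraction)
    if tail_q < tail_quality_floor:
        return StrategyRecommendation(
            "single_forward",
            f"reverse tail quality: mean Q{tail_q:.1f} over the last "
            f"{tail_fraction:.0%} of positions is below Q{tail_quality_floor:g}",
        )
    return StrategyRecommendation(
        "paired",
        f"expected overlap {plan.expected_overlap} nt >= "
        f"{plan.model.min_overlap} nt and reverse tail mean Q{tail_q:.1f} "
        f">= Q{tail_quality_floor:g}",
    )
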