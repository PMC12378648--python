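"""Synthetic paired-end FASTQ with a parameterized quality-decay model.

Emulates the quality geometry of an Illumina MiSeq 2x300 amplicon run:
per-cycle expected quality sits on a high plateau, then decays to a low
tail after a configurable breakpoint, either as a hard step or a
sigmoid.  Per-base Gaussian jitter (applied to the PHRED score directly,
clamped to [2, 41] as MiSeq scores are, then rounded) makes the reads
noisy while keeping the per-cycle expectation on the model curve.

Base composition is uniform random — the truncation algorithm is purely
quality-driven, so sequence content is deliberately uninformative.  Real
error-profile features (substitution spectra, indels, chimeras) are out
of scope.

``expected_truncation`` is the analytic oracle: for a noiseless spec it
applies the crossing rule to the model curve itself, giving the ground
truth the detector should recover from simulated files.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np

from .fastq_io import ReadRecord, write_fastq

Q_MIN, Q_MAX = 2, 41  # MiSeq score range after clamping

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the quality-decay read generator.

    ``breakpoint`` is the last high-quality cycle (decay begins after
    it); ``slope`` is the sigmoid width in cycles (ignored for ``step``).
    ``amplicon_len`` is the nominal template length, carried as metadata
    for overlap planning; reads always span ``read_len`` cycles.
    """

    n_reads: int
    read_len: int = 300
    q_high: int = 38
    q_low: int = 15
    breakpoint: int = 200
    decay: str = "step"  # "step" | "sigmoid"
    slope: float = 10.0
    jitter_sd: float = 0.0
    amplicon_len: int = 330
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 1 <= self.breakpoint <= self.read_len:
            raise ValueError("require 1 <= breakpoint <= read_len")
        if not self.q_low < self.q_high <= Q_MAX:
            raise ValueError(f"require q_low < q_high <= {Q_MAX}")
        if self.decay not in ("step", "sigmoid"):
            raise ValueError(f"unknown decay model {self.decay!r}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimSummary:
    n_r1: int
    n_r2: int
    r1_path: str
    r2_path: str


def model_curve(spec: SimSpec) -> np.ndarray:
    """Expected (pre-jitter) quality at cycles 1..read_len, as floats."""
    p = np.arange(1, spec.read_len + 1, dtype=float)
    if spec.decay == "step":
        return np.where(p <= spec.breakpoint, float(spec.q_high), float(spec.q_low))
    drop = spec.q_high - spec.q_low
    return spec.q_high - drop / (1.0 + np.exp(-(p - spec.breakpoint) / spec.slope))


def quantized_curve(spec: SimSpec) -> np.ndarray:
    """The model curve as emitted scores: rounded and clamped to [2, 41]."""
    return np.clip(np.rint(model_curve(spec)), Q_MIN, Q_MAX).astype(np.uint8)


def expected_truncation(spec: SimSpec) -> int:
    """Analytic truncation length for a noiseless spec.

    With ``jitter_sd == 0`` every read carries the quantized model curve,
    so the per-cycle median equals that curve and the grand mean is its
    average; the crossing rule is then evaluated in closed form.  Returns
    ``read_len`` when the curve never drops strictly below its mean.
    """
    if spec.jitter_sd != 0:
        raise ValueError("expected_truncation is defined for jitter_sd == 0")
    curve = quantized_curve(spec).astype(float)
    grand_mean = curve.mean()
    below = np.nonzero(curve < grand_mean)[0]
    if below.size == 0:
        return spec.read_len
    if below[0] == 0:
        raise ValueError("model curve crosses its mean at cycle 1")
    return int(below[0])  # first crossing is 1-based position below[0]+1


def simulate_reads(
    spec: SimSpec, rng: np.random.Generator, id_prefix: str = "sim"
) -> Iterator[ReadRecord]:
    """Yield ``spec.n_reads`` records drawn from the decay model."""
    curve = model_curve(spec)
    batch = 1000
    emitted = 0
    while emitted < spec.n_reads:
        n = min(batch, spec.n_reads - emitted)
        base_idx = rng.integers(0, 4, size=(n, spec.read_len))
        seqs = _BASES[base_idx]
        if spec.jitter_sd > 0:
            q = rng.normal(curve, spec.jitter_sd, size=(n, spec.read_len))
        else:
            q = np.broadcast_to(curve, (n, spec.read_len))
        q = np.clip(np.rint(q), Q_MIN, Q_MAX).astype(np.uint8)
        for i in range(n):
            yield ReadRecord(
                f"{id_prefix}_{emitted + i + 1:07d}",
                seqs[i].tobytes().decode("ascii"),
                q[i],
            )
        emitted += n


def simulate_pairs(
    spec_forward: SimSpec,
    spec_reverse: SimSpec,
    out_r1: Union[str, Path],
    out_r2: Union[str, Path],
    seed: Optional[int] = None,
) -> SimSummary:
    """Write a paired run (R1/R2 FASTQ, gzip when the name ends ``.gz``).

    One master seed (``seed``, defaulting to ``spec_forward.seed``) is
    split deterministically into independent per-direction streams, so
    identical specs and seed reproduce byte-identical files.
    """
    master = spec_forward.seed if seed is None else seed
    child_f, child_r = np.random.SeedSequence(master).spawn(2)
    n1 = write_fastq(
        simulate_reads(spec_forward, np.random.default_rng(child_f), "sim_fwd"),
        out_r1,
    )
    n2 = write_fastq(
        simulate_reads(spec_reverse, np.random.default_rng(child_r), "sim_rev"),
        out_r2,
    )
    return SimSummary(n1, n2, str(out_r1), str(out_r2))
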