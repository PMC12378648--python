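# Methods

## The problem

DADA2 denoises paired-end amplicon reads after a fixed truncation:
`--p-trunc-len-f`/`--p-trunc-len-r` cut every forward/reverse read at the
same cycle, discarding reads that are shorter. Choosing those two lengths is
a trade-off: truncate too late and the noisy 3' tail inflates the error
model and kills reads at the max-EE filter; truncate too early and the pair
no longer spans the amplicon with the ≥ 12 nt overlap DADA2 needs to merge.
On ITS amplicons the problem is acute because reverse MiSeq reads degrade
much earlier than forward reads. This package automates the choice from
per-cycle quality statistics.

## The truncation rule

For each FASTQ file the per-cycle quality profile is computed exactly:
coverage `c_p`, mean `m_p` and median `M_p` of the PHRED scores at cycle
`p`, plus the file's grand-mean quality

    Q̄ = (Σ_p Σ_reads q_{read,p}) / (total base calls).

The file's truncation point is

    trunc = p* − 1,  p* = min { p : M_p < Q̄ },

i.e. keep all cycles strictly before the first one whose median drops
strictly below the file average; if no cycle crosses, the full profiled
length is kept. On typical Illumina profiles — a long high plateau followed
by a decay — the crossing sits where the quality curve falls through the
file average, close to the point of steepest decline. The rule is the
*first* strict crossing, not a sustained-run rule; a median exactly equal to
the average never triggers. A crossing at cycle 1 (whole file below its own
average, possible only for pathological ragged input) is an error rather
than a zero-length plan.

Per-direction aggregation is the arithmetic mean of the per-file truncation
points, rounded **down** — when the mean is fractional, cutting one cycle
more is safer for the downstream error model than keeping a below-average
cycle. The convention is fixed and tested.

## The overlap constraint

With truncation lengths `r1`, `r2` and expected amplicon length `L`, the
expected merge overlap is `r1 + r2 − L`. If it falls below the minimum
`m` (default 12 nt), only the forward truncation is raised:

    r1_final = min(L + m − r2,  max_read_len),   r2_final = r2  (always),

because forward cycles are the higher-quality ones — lengthening the reverse
read would add exactly the noise the truncation removed. `r1_final` is the
smallest integer restoring the overlap (minimality is property-tested). If
even the full read length cannot reach the overlap the plan is flagged
`feasible = false`; that is a reported state, and the strategy advisor then
recommends forward-only (single-end) denoising. The advisor also recommends
single-end when the mean per-cycle quality over the last 20% of reverse
positions is below a floor (default Q20, configurable): reverse tails that
poor tend to defeat merging even when the geometry works. Both thresholds
are judgment-call defaults exposed in the config, not estimated quantities.

`L` is a required input. For length-variable markers like ITS1 there is no
single true amplicon length; users should supply a conservative (long)
percentile of the expected length distribution, since a longer `L` yields a
larger, safer `r1_final`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_overlap` | 12 nt | minimum forward/reverse overlap for merging |
| `trim_left` | 5 nt | leading bases removed from every read |
| `max_read_len` | 300 | sequencing cycles (MiSeq 2×300) |
| `tail_quality_floor` | Q20 | reverse-tail mean below this ⇒ single-end advice |
| tail fraction | 20 % | portion of reverse positions averaged for the tail check |
| `amplicon_len` | — (required) | expected template length `L` |

## Trimming semantics

`truncate_and_trim` discards reads strictly shorter than `trunc_len`
(reads exactly `trunc_len` long are kept), cuts survivors to `trunc_len`
in raw-read coordinates, then removes the first `trim_left` bases. Order
matters and is deliberate: truncating before left-trimming keeps
`trunc_len` in the same cycle coordinates the quality profile indexed, so a
planned length can be read directly off a profile plot. Every output read
has length `trunc_len − trim_left`, and input count = output + discarded.

## Quality profiling internals

Statistics are exact, not FastQC-binned: a streaming histogram of 94 PHRED
bins per cycle gives exact medians (even counts: mean of the two central
values, so half-integers occur) in O(read_len × 94) memory regardless of
file size. Positions reached by fewer than 1% of reads are excluded from
the profile and can never become truncation points — the median of a
handful of straggler reads is noise; for fixed-length Illumina input no
position is ever excluded. The grand mean is over *all* base calls,
including any excluded tail. 'N' bases carry their reported quality and are
not masked. PHRED encoding is auto-detected from up to the first 10,000
quality characters (any character below ASCII 64 ⇒ phred33; all within
[64, 74] ⇒ formally ambiguous, resolved to phred33 with a warning since all
current instruments emit phred33; otherwise phred64); gzip is recognised by
magic bytes so renamed files parse fine.

## The simulator and what passing tests mean

`sim_reads` generates paired FASTQ whose per-cycle expected quality follows
a plateau/decay curve: plateau `q_high` (default Q38) through a breakpoint
cycle (defaults: 200 forward, 160 reverse — reverse reads decay earlier, as
on a real 2×300 ITS run), then tail `q_low` (default Q15), as a hard step
or a sigmoid of configurable width. Gaussian jitter (default sd 2) is added
to the PHRED score directly, rounded and clamped to [2, 41] (the MiSeq
score range); bases are uniform random because the algorithm is purely
quality-driven. One master seed is split with `numpy.random.SeedSequence.spawn`
into independent forward/reverse streams, making paired files byte-reproducible.

`expected_truncation` is the analytic oracle: for a noiseless spec every
read carries the quantized model curve, so the per-cycle median *is* that
curve and the crossing rule evaluates in closed form. The recovery tests
(20 seeds × 5,000 reads × 300 cycles, step decay, jitter sd 2) demand the
detector land within ±2 cycles of the oracle in ≥ 95% of seeds.

What the simulator does **not** emulate: substitution/indel error spectra,
chimeras, length-variable amplicons, quality–base correlations, tile and
flow-cell effects, or FastQC-style binned scores. Passing tests therefore
show that the detector recovers a known quality-decay geometry under
Gaussian score noise — not that any particular truncation is optimal for a
real community profile.

## Numerical and degenerate-input choices

- Medians and the crossing comparison are exact integer/half-integer
  arithmetic against a float grand mean; no tolerance is involved, the
  inequality is strict.
- Empty input, all-empty reads, and a cycle-1 crossing are errors with
  stage-named messages; overlap infeasibility is a reported flag, not an
  error.
- Aggregation floor, discard-if-strictly-shorter, and keep-if-equal
  tie-breaks are fixed conventions, each pinned by a test.
- The planner removes partial artifacts when a stage fails, so an output
  directory never holds a half-written plan.

## Known limitations

- One truncation pair per run direction: per-sample heterogeneity is
  averaged away (all provided files of a direction contribute equally).
- `amplicon_len` is trusted, not estimated; a wrong value silently shifts
  the overlap constraint.
- The tail-quality advisory uses the last reverse profile of the run as the
  direction's representative when several reverse files are given.
- Reports and env files assume a POSIX shell consumer (`R1TRUN=…`,
  `R2TRUN=…` assignments only).
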