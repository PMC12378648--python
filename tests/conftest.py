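import numpy as np
import pytest

from autotrunc import ReadRecord, write_fastq


def make_record(read_id, quals, bases=None):
    quals = np.asarray(quals, dtype=np.uint8)
    if bases is None:
        bases = "A" * quals.size
    return ReadRecord(read_id, bases, quals)


def random_records(rng, n_reads, max_len, ragged=True):
    """Small random reads for oracle comparisons."""
    records = []
    for i in range(n_reads):
        length = int(rng.integers(1, max_len + 1)) if ragged else max_len
        quals = rng.integers(0, 42, size=length)
        bases = "".join(rng.choice(list("ACGTN"), size=length))
        records.append(ReadRecord(f"r{i}", bases, quals.astype(np.uint8)))
    return records


@pytest.fixture
def fastq_file(tmp_path):
    """Factory writing records to a FASTQ file, returning its path."""

    def _write(records, name="reads.fastq"):
        path = tmp_path / name
        write_fastq(records, path)
        return path

    return _write


@pytest.fixture
def micro_matrix_records():
    """Three 4-cycle reads whose profile is known in closed form:
    per-position medians (40, 38, 25, 10), grand mean 339/12 = 28.25."""
    return [
        make_record("a", [40, 40, 30, 10]),
        make_record("b", [40, 38, 20, 10]),
        make_record("c", [38, 36, 25, 12]),
    ]
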