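from __future__ import annotations

import pytest

from chiascan import DetectionParams, GenomeSequence, ReadRecord, SimulationConfig, simulate_dataset


@pytest.fixture
def params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def small_sim():
    """A small planted dataset shared by several end-to-end tests."""
    config = SimulationConfig(
        genome_len=20_000,
        n_circ=5,
        circ_size_range=(100, 2000),
        reads_per_circ=12,
        background_reads=300,
        seed=11,
    )
    return simulate_dataset(config)


def make_genome(seq: str, ref_id: str = "chr") -> dict[str, GenomeSequence]:
    return {ref_id: GenomeSequence(ref_id, seq.upper())}


def make_read(seq: str, read_id: str = "r1") -> ReadRecord:
    return ReadRecord(read_id, seq.upper())
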