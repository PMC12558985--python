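"""Synthetic-data generator: determinism, geometry, planted-truth guarantees."""

from __future__ import annotations

import numpy as np
import pytest

from chiascan import DetectionParams, SimulationConfig, detect_all, revcomp, simulate_dataset, write_dataset
from chiascan.simulate import plant_circles, simulate_genome


def small_config(**kw):
    defaults = dict(
        genome_len=15_000,
        n_circ=4,
        circ_size_range=(100, 1500),
        reads_per_circ=10,
        background_reads=100,
        seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_identical_seeds_identical_outputs(tmp_path):
    d1 = simulate_dataset(small_config())
    d2 = simulate_dataset(small_config())
    assert d1.genome.sequence == d2.genome.sequence
    assert [(r.read_id, r.sequence) for r in d1.reads] == [
        (r.read_id, r.sequence) for r in d2.reads
    ]
    p1 = write_dataset(d1, tmp_path / "a")
    p2 = write_dataset(d2, tmp_path / "b")
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes()


def test_different_seed_differs():
    assert (
        simulate_dataset(small_config()).genome.sequence
        != simulate_dataset(small_config(seed=4)).genome.sequence
    )


def test_genome_length_and_composition():
    config = small_config(genome_len=40_000)
    genome = simulate_genome(config)
    assert genome.length == 40_000
    counts = {b: genome.sequence.count(b) for b in "ACGT"}
    assert sum(counts.values()) == 40_000
    # each base ~ Binomial(n, 1/4); 5 sigma band
    n, p = 40_000, 0.25
    sigma = (n * p * (1 - p)) ** 0.5
    for b, c in counts.items():
        assert abs(c - n * p) < 5 * sigma, (b, c)


def test_planted_circles_disjoint_in_range_with_unique_flanks():
    config = small_config(n_circ=6, genome_len=30_000)
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    truths = plant_circles(genome, config, rng)
    assert len(truths) == 6
    intervals = sorted((t.start, t.end) for t in truths)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        assert e1 <= s2
    lo, hi = config.circ_size_range
    seq, rc = genome.sequence, revcomp(genome.sequence)
    for t in truths:
        assert lo <= t.end - t.start <= hi
        # exhaustive scan: junction-flanking 8-mers unique on both strands
        for kmer in (seq[t.start : t.start + 8], seq[t.end - 8 : t.end]):
            assert seq.count(kmer) + rc.count(kmer) == 1


def test_junction_read_geometry_matches_construction():
    config = small_config(fraction_minus_strand=0.0, protocol_inverted=False)
    ds = simulate_dataset(config)
    seq = ds.genome.sequence
    by_circ = {t.circ_id: t for t in ds.truths}
    checked = 0
    for read in ds.reads:
        if read.read_id.startswith("bg_"):
            continue
        circ_id = read.read_id.rsplit("_read", 1)[0]
        t = by_circ[circ_id]
        # read = genome[end-a, end) + genome[start, start+b) for some split
        found = any(
            read.sequence == seq[t.end - a : t.end] + seq[t.start : t.start + (40 - a)]
            for a in range(8, 33)
        )
        assert found, read.read_id
        checked += 1
    assert checked == sum(t.n_junction_reads_emitted for t in ds.truths)


def test_insert_bases_appear_in_every_junction_read_and_in_calls():
    config = small_config(
        insert_junction_bases="CCA", fraction_minus_strand=0.0, protocol_inverted=False
    )
    ds = simulate_dataset(config)
    params = DetectionParams(invert_strand=False)
    junctions = detect_all(ds.reads, {ds.genome.ref_id: ds.genome}, params)
    truth_keys = {(t.start, t.end): t for t in ds.truths}
    assert len(junctions) == len(ds.truths)
    for j in junctions:
        assert (j.start, j.end) in truth_keys
        assert j.inserted_bases == "CCA"
        assert truth_keys[(j.start, j.end)].read_space_insert == "CCA"


def test_inverted_protocol_reports_transcript_strand():
    config = small_config(fraction_minus_strand=0.5, protocol_inverted=True, seed=8)
    ds = simulate_dataset(config)
    junctions = detect_all(ds.reads, {ds.genome.ref_id: ds.genome}, DetectionParams())
    got = {(j.start, j.end): j.strand for j in junctions}
    for t in ds.truths:
        assert got[(t.start, t.end)] == t.strand


def test_full_error_rate_destroys_junction_support():
    """With a substitution in every read, reads whose error falls inside an
    aligned segment are rejected by the mismatch filter; only errors in the
    outermost (uncovered) read bases can slip through, so no circle retains
    more than a small fraction of its support and nothing is significant."""
    from chiascan import filter_significant, group_junctions

    config = small_config(per_read_error_rate=1.0)
    ds = simulate_dataset(config)
    junctions = detect_all(ds.reads, {ds.genome.ref_id: ds.genome}, DetectionParams())
    assert filter_significant(group_junctions(junctions), 10) == []
    support = {(j.start, j.end): len(j.read_ids) for j in junctions}
    for t in ds.truths:
        assert support.get((t.start, t.end), 0) < t.n_junction_reads_emitted


def test_duplicated_flank_defeats_uniqueness_filter():
    """Repetitive context (e.g. an IS copy) makes junction segments
    multi-placed; the uniqueness filter then drops those reads."""
    config = small_config(n_circ=2, background_reads=0, fraction_minus_strand=0.0)
    ds = simulate_dataset(config)
    t = ds.truths[0]
    seq = ds.genome.sequence
    # duplicate a 60 nt block spanning the circle 5' flank far away
    block = seq[t.start : t.start + 60]
    dup_seq = seq[: 14_000] + block + seq[14_000 + 60 :]
    assert dup_seq != seq and len(dup_seq) == len(seq)
    genome2 = {ds.genome.ref_id: type(ds.genome)(ds.genome.ref_id, dup_seq)}
    junctions = detect_all(ds.reads, genome2, DetectionParams())
    found = {(j.start, j.end) for j in junctions}
    assert (t.start, t.end) not in found  # suffix segment now multi-placed
    other = ds.truths[1]
    assert (other.start, other.end) in found  # untouched circle unaffected


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(genome_len=500)
    with pytest.raises(ValueError):
        SimulationConfig(circ_size_range=(30, 3500), read_len=40)
    with pytest.raises(ValueError):
        SimulationConfig(per_read_error_rate=1.5)
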