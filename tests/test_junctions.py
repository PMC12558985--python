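"""Chiastic pairing, junction filters, coordinate resolution, per-read calls."""

from __future__ import annotations

import random

import pytest

from chiascan import (
    AlignmentHit,
    DetectionParams,
    GenomeSequence,
    ReadRecord,
    apply_filters,
    detect_all,
    pair_candidates,
    resolve_junction,
)
from chiascan.junctions import JunctionCandidate, _resolved_extent

from conftest import make_genome, make_read


def hit(read_start, read_end, ref_start, ref_end, strand="+", read_id="r1", ref_id="chr"):
    return AlignmentHit(read_id, read_start, read_end, ref_id, ref_start, ref_end, strand)


def candidate(prefix, suffix, read, params=None):
    cands = pair_candidates([prefix, suffix], read, params or DetectionParams())
    assert len(cands) <= 1
    return cands[0] if cands else None


@pytest.fixture
def plain_params():
    # read strand reported directly: easier geometric assertions
    return DetectionParams(invert_strand=False)


def test_canonical_chiastic_pair(plain_params):
    read = make_read("A" * 30)
    c = candidate(hit(0, 15, 185, 200), hit(15, 30, 100, 115), read, plain_params)
    assert c is not None
    assert (c.overlap_len, c.gap_len, c.coverage) == (0, 0, 1.0)
    j = resolve_junction(c, plain_params)
    assert (j.start, j.end, j.strand) == (100, 200, "+")


def test_colinear_pair_is_not_chiastic(plain_params):
    read = make_read("A" * 30)
    assert candidate(hit(0, 15, 100, 115), hit(15, 30, 115, 130), read, plain_params) is None


def test_gap_bases_recorded_verbatim(plain_params):
    seq = "G" * 15 + "CCA" + "T" * 15
    read = make_read(seq)
    c = candidate(hit(0, 15, 185, 200), hit(18, 33, 100, 115), read, plain_params)
    assert (c.gap_len, c.inserted_bases) == (3, "CCA")
    j = resolve_junction(c, plain_params)
    assert j.inserted_bases == "CCA"


def test_strand_reporting_modes():
    read = make_read("A" * 30)
    prefix, suffix = hit(0, 15, 185, 200), hit(15, 30, 100, 115)
    for params, expected in [
        (DetectionParams(invert_strand=False), "+"),
        (DetectionParams(invert_strand=True), "-"),
        (DetectionParams(strand_specific=False), "."),
    ]:
        c = candidate(prefix, suffix, read, params)
        assert resolve_junction(c, params).strand == expected


def test_overlap_assigned_to_prefix_segment(plain_params):
    # overlap 2: junction bases stay with the read-prefix (transcript 3') side
    read = make_read("A" * 28)
    c = candidate(hit(0, 15, 185, 200), hit(13, 28, 100, 115), read, plain_params)
    assert c.overlap_len == 2
    j = resolve_junction(c, plain_params)
    assert (j.start, j.end) == (102, 200)


def test_minus_strand_mirrored_geometry(plain_params):
    read = make_read("A" * 30)
    c = candidate(
        hit(0, 15, 100, 115, strand="-"), hit(15, 30, 185, 200, strand="-"), read, plain_params
    )
    assert c is not None
    j = resolve_junction(c, plain_params)
    assert (j.start, j.end, j.strand) == (100, 200, "-")
    # overlap trimming on '-' shortens the genomic end (transcript 3' side)
    read2 = make_read("A" * 28)
    c2 = candidate(
        hit(0, 15, 100, 115, strand="-"), hit(13, 28, 185, 200, strand="-"), read2, plain_params
    )
    assert resolve_junction(c2, plain_params).end == 198


@pytest.mark.parametrize("overlap,expected", [(3, True), (4, False)])
def test_overlap_tolerance_boundary(overlap, expected, plain_params):
    read = make_read("A" * 40)
    c = candidate(
        hit(0, 20, 1180, 1200), hit(20 - overlap, 40 - overlap, 100, 120), read, plain_params
    )
    assert (c is not None) is expected


@pytest.mark.parametrize("gap,expected", [(3, True), (4, False)])
def test_gap_tolerance_boundary(gap, expected, plain_params):
    read = make_read("A" * 40)
    c = candidate(hit(0, 18, 1182, 1200), hit(18 + gap, 40, 100, 122 - gap), read, plain_params)
    assert (c is not None) is expected


def test_filter_pass_example(plain_params):
    # 40 nt read, segments 25 + 14 with a 1 nt gap: union 39/40, best 25, other 14
    read = make_read("A" * 40)
    c = candidate(hit(0, 25, 1000, 1025), hit(26, 40, 500, 514), read, plain_params)
    assert apply_filters(c, read, plain_params) == (True, None)


def test_filter_secondary_segment_boundary(plain_params):
    read = make_read("A" * 40)
    ok = candidate(hit(0, 30, 1000, 1030), hit(32, 40, 500, 508), read, plain_params)
    assert apply_filters(ok, read, plain_params).ok  # 8 nt secondary passes
    bad = candidate(hit(0, 30, 1000, 1030), hit(33, 40, 500, 507), read, plain_params)
    result = apply_filters(bad, read, plain_params)
    assert (result.ok, result.reason) == (False, "min_other_len")


@pytest.mark.parametrize(
    "span,expected_reason", [(3500, None), (3501, "max_span")]
)
def test_span_boundary(span, expected_reason, plain_params):
    read = make_read("A" * 40)
    c = candidate(hit(0, 20, span - 20, span), hit(20, 40, 0, 20), read, plain_params)
    result = apply_filters(c, read, plain_params)
    assert result.reason == expected_reason
    assert result.ok is (expected_reason is None)


@pytest.mark.parametrize("suffix_end,expected_ok", [(950, True), (949, False)])
def test_union_coverage_boundary(suffix_end, expected_ok):
    # read of 1000 nt with unaligned edges: prefix covers [50, 550), suffix
    # [550, suffix_end); union 900 -> coverage 0.90 passes, 899 -> 0.899 fails
    params = DetectionParams(invert_strand=False, min_best_fraction=0.5)
    read = make_read("A" * 1000)
    suffix_len = suffix_end - 550
    c = candidate(
        hit(50, 550, 4000, 4500), hit(550, suffix_end, 1000, 1000 + suffix_len), read, params
    )
    result = apply_filters(c, read, params)
    if expected_ok:
        assert result.ok
    else:
        assert result.reason == "min_read_cov"


def test_best_segment_half_read_rule():
    params = DetectionParams(invert_strand=False)
    read = make_read("A" * 40)
    # best 19/40 < 0.5 even though coverage passes
    c = candidate(hit(0, 19, 1000, 1019), hit(19, 38, 500, 519), read, params)
    assert apply_filters(c, read, params).reason == "min_best_fraction"


def test_degenerate_resolution_discarded(plain_params):
    # overlap trimming assigns junction bases to the prefix: (103, 116) here
    c = JunctionCandidate(
        read_id="r1",
        prefix_hit=hit(0, 15, 101, 116),
        suffix_hit=hit(12, 27, 100, 115),
        overlap_len=3,
        gap_len=0,
        inserted_bases="",
        coverage=27 / 28,
    )
    assert _resolved_extent(c) == (103, 116)
    # a span swallowed entirely by the trim is degenerate and discarded
    degenerate = JunctionCandidate(
        read_id="r1",
        prefix_hit=hit(0, 2, 100, 102),
        suffix_hit=hit(1, 3, 99, 101),
        overlap_len=3,
        gap_len=0,
        inserted_bases="",
        coverage=1.0,
    )
    assert _resolved_extent(degenerate) is None
    assert resolve_junction(degenerate, plain_params) is None


def _build_ambiguous_fixture():
    """A read with two equally good chiastic explanations at different loci.

    The read is X+Y+Z (three 10-mers).  XY and Z are planted so that
    (prefix XY, suffix Z) is chiastic at one locus; X and YZ are planted so
    that (prefix X, suffix YZ) is chiastic at another.  Guard bases stop
    the planted copies from extending into their random context.
    """
    rng = random.Random(99)
    x = "".join(rng.choice("ACGT") for _ in range(10))
    y = "".join(rng.choice("ACGT") for _ in range(10))
    z = "".join(rng.choice("ACGT") for _ in range(10))
    g = [rng.choice("ACGT") for _ in range(800)]

    def other(base):
        return "A" if base != "A" else "C"

    g[100:110] = z
    g[300:320] = x + y
    g[500:520] = y + z
    g[700:710] = x
    g[99] = other(y[9])   # Z not left-extendable
    g[320] = other(z[0])  # XY not right-extendable
    g[499] = other(x[9])  # YZ not left-extendable
    g[710] = other(y[0])  # X not right-extendable
    return "".join(g), x + y + z


def test_ambiguous_read_contributes_to_no_junction():
    genome_seq, read_seq = _build_ambiguous_fixture()
    genome = make_genome(genome_seq)
    params = DetectionParams(invert_strand=False, min_read_len=20)
    assert detect_all([ReadRecord("amb", read_seq)], genome, params) == []


def test_detect_all_merges_read_support(small_sim):
    genome = {small_sim.genome.ref_id: small_sim.genome}
    junctions = detect_all(small_sim.reads, genome)
    by_key = {(j.start, j.end, j.strand): j for j in junctions}
    for truth in small_sim.truths:
        j = by_key[(truth.start, truth.end, truth.strand)]
        assert len(j.read_ids) == truth.n_junction_reads_emitted


def test_no_chiastic_reads_yields_empty(small_sim):
    genome = {small_sim.genome.ref_id: small_sim.genome}
    background_only = [r for r in small_sim.reads if r.read_id.startswith("bg_")]
    assert detect_all(background_only, genome) == []
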