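"""Circularization-junction calling from chiastic split alignments.

A read crossing the circularization junction of a circRNA aligns in two
segments whose genomic order is swapped relative to their order in the read
(chiastic geometry): the read's 5' segment maps genomically downstream of
its 3' segment.  This module pairs the filtered alignment hits of each read
into such candidates, applies the coverage/length/span filters, resolves
the junction's genomic coordinates (trimming any overlap, recording any
untemplated inserted bases in the gap), and merges the per-read calls into
junction records.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .align import AlignmentHit, ExactMatchIndex, filter_hits
from .io import GenomeSequence, ReadRecord

logger = logging.getLogger(__name__)

_FLIP = {"+": "-", "-": "+", ".": "."}


@dataclass
class DetectionParams:
    """Thresholds of the junction-calling method.

    max_span
        Maximum circRNA size in nt: the resolved junction span
        ``end - start`` may not exceed it.
    min_read_cov
        The two segments together must cover at least this fraction of the
        read (union of read intervals; overlapping bases counted once).
    min_best_fraction
        The longer of the two segments must cover at least this fraction of
        the read.
    min_other_len
        The shorter segment must be at least this many nt.
    max_overlap / max_gap
        Read bases at the junction claimed by both segments (overlap) or by
        neither (gap) are tolerated up to these lengths.
    group_tol
        Coordinate tolerance used downstream for ensemble grouping and for
        junction matching across datasets.
    min_reads
        Read-support threshold for a significant circRNA.
    invert_strand
        Flip the reported strand (dUTP-type stranded libraries sequence the
        strand antisense to the transcript).
    strand_specific
        When false, all junctions are reported on strand "." so junctions
        from both read strands group together.
    min_read_len
        Reads shorter than this are ignored.
    """

    max_span: int = 3500
    min_read_cov: float = 0.90
    min_best_fraction: float = 0.50
    min_other_len: int = 8
    max_overlap: int = 3
    max_gap: int = 3
    group_tol: int = 3
    min_reads: int = 10
    invert_strand: bool = True
    strand_specific: bool = True
    min_read_len: int = 20

    def __post_init__(self) -> None:
        for name in ("max_span", "min_other_len", "max_overlap", "max_gap",
                     "group_tol", "min_reads", "min_read_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("min_read_cov", "min_best_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class JunctionCandidate:
    """A chiastic pair of hits from one read, with junction bookkeeping."""

    read_id: str
    prefix_hit: AlignmentHit  # covers the read's 5' segment
    suffix_hit: AlignmentHit  # covers the read's 3' segment
    overlap_len: int
    gap_len: int
    inserted_bases: str
    coverage: float

    @property
    def best_len(self) -> int:
        return max(self.prefix_hit.read_len, self.suffix_hit.read_len)

    @property
    def other_len(self) -> int:
        return min(self.prefix_hit.read_len, self.suffix_hit.read_len)


@dataclass
class CircJunction:
    """A resolved circularization junction with its supporting reads."""

    ref_id: str
    start: int  # genomic 5' boundary, 0-based inclusive
    end: int  # genomic 3' boundary, exclusive
    strand: str
    read_ids: set[str]
    inserted_bases: str = ""
    # read_id -> (overlap_len, gap_len) of the call; not part of identity
    read_detail: dict[str, tuple[int, int]] = field(default_factory=dict, compare=False)

    @property
    def key(self) -> tuple[str, str, int, int, str]:
        return (self.ref_id, self.strand, self.start, self.end, self.inserted_bases)

    @property
    def span(self) -> int:
        return self.end - self.start


class FilterResult(NamedTuple):
    ok: bool
    reason: str | None


def pair_candidates(
    hits_of_one_read: Sequence[AlignmentHit],
    read: ReadRecord,
    params: DetectionParams,
) -> list[JunctionCandidate]:
    """Enumerate chiastic (prefix, suffix) hit pairs of one read.

    A pair qualifies when both hits share ref and strand, the prefix hit
    precedes the suffix hit in read coordinates with at most ``max_overlap``
    shared or ``max_gap`` uncovered junction bases, and the genomic order is
    swapped: on strand "+" the suffix segment maps upstream of the prefix
    segment (mirrored on strand "-").
    """
    by_group: dict[tuple[str, str], list[AlignmentHit]] = defaultdict(list)
    for h in hits_of_one_read:
        by_group[(h.ref_id, h.strand)].append(h)
    candidates = []
    read_len = read.length
    for (_, strand), group in sorted(by_group.items()):
        for prefix in group:
            for suffix in group:
                if not (prefix.read_start < suffix.read_start and prefix.read_end < suffix.read_end):
                    continue
                overlap = max(0, prefix.read_end - suffix.read_start)
                gap = max(0, suffix.read_start - prefix.read_end)
                if overlap > params.max_overlap or gap > params.max_gap:
                    continue
                if strand == "+":
                    chiastic = suffix.ref_start < prefix.ref_start
                else:
                    chiastic = suffix.ref_start > prefix.ref_start
                if not chiastic:
                    continue
                covered = prefix.read_len + suffix.read_len - overlap
                candidates.append(
                    JunctionCandidate(
                        read_id=read.read_id,
                        prefix_hit=prefix,
                        suffix_hit=suffix,
                        overlap_len=overlap,
                        gap_len=gap,
                        inserted_bases=read.sequence[prefix.read_end : suffix.read_start],
                        coverage=covered / read_len,
                    )
                )
    return candidates


def _resolved_extent(candidate: JunctionCandidate) -> tuple[int, int] | None:
    """Genomic (start, end) of the junction, overlap assigned to the prefix.

    Ambiguous junction bases (claimable by either segment) are kept by the
    read-prefix segment — the transcript's 3' side — and trimmed from the
    suffix segment.  Returns None for degenerate geometry (start >= end).
    """
    o = candidate.overlap_len
    if candidate.prefix_hit.strand == "+":
        start = candidate.suffix_hit.ref_start + o
        end = candidate.prefix_hit.ref_end
    else:
        start = candidate.prefix_hit.ref_start
        end = candidate.suffix_hit.ref_end - o
    if start >= end:
        return None
    return start, end


def apply_filters(
    candidate: JunctionCandidate,
    read: ReadRecord,
    params: DetectionParams,
) -> FilterResult:
    """Check the four junction filters; failure names the first violated rule."""
    read_len = read.length
    if candidate.coverage < params.min_read_cov:
        return FilterResult(False, "min_read_cov")
    if candidate.best_len < params.min_best_fraction * read_len:
        return FilterResult(False, "min_best_fraction")
    if candidate.other_len < params.min_other_len:
        return FilterResult(False, "min_other_len")
    extent = _resolved_extent(candidate)
    if extent is None:
        return FilterResult(False, "degenerate")
    if extent[1] - extent[0] > params.max_span:
        return FilterResult(False, "max_span")
    return FilterResult(True, None)


def resolve_junction(
    candidate: JunctionCandidate,
    params: DetectionParams,
) -> CircJunction | None:
    """Turn a passing candidate into a junction record.

    The reported strand is the read strand, flipped when
    ``params.invert_strand`` (stranded protocols sequencing the antisense
    strand), or "." when not ``params.strand_specific``.
    """
    extent = _resolved_extent(candidate)
    if extent is None:
        return None
    start, end = extent
    strand = candidate.prefix_hit.strand
    if params.invert_strand:
        strand = _FLIP[strand]
    if not params.strand_specific:
        strand = "."
    return CircJunction(
        ref_id=candidate.prefix_hit.ref_id,
        start=start,
        end=end,
        strand=strand,
        read_ids={candidate.read_id},
        inserted_bases=candidate.inserted_bases,
        read_detail={candidate.read_id: (candidate.overlap_len, candidate.gap_len)},
    )


def best_candidate(
    candidates: Sequence[JunctionCandidate],
    read: ReadRecord,
    params: DetectionParams,
) -> JunctionCandidate | None:
    """Per-read selection: max coverage, then longer best segment.

    A read whose tied-best candidates resolve to *different* junctions is
    ambiguous and contributes to none; ties that resolve to the same
    junction keep one arbitrarily (they are the same call).
    """
    passing = [c for c in candidates if apply_filters(c, read, params).ok]
    if not passing:
        return None
    best_key = max((c.coverage, c.best_len) for c in passing)
    tied = [c for c in passing if (c.coverage, c.best_len) == best_key]
    if len(tied) > 1:
        resolved = {
            (c.prefix_hit.ref_id, c.prefix_hit.strand, _resolved_extent(c), c.inserted_bases)
            for c in tied
        }
        if len(resolved) > 1:
            return None
    return tied[0]


def _merge_calls(calls: Iterable[CircJunction]) -> list[CircJunction]:
    merged: dict[tuple, CircJunction] = {}
    for call in calls:
        j = merged.get(call.key)
        if j is None:
            merged[call.key] = call
        else:
            j.read_ids |= call.read_ids
            j.read_detail.update(call.read_detail)
    return sorted(merged.values(), key=lambda j: (j.ref_id, j.start, j.end, j.strand))


def detect_from_hits(
    reads: Sequence[ReadRecord],
    hits: Sequence[AlignmentHit],
    params: DetectionParams | None = None,
    prefiltered: bool = False,
) -> list[CircJunction]:
    """Junction calling from an existing hit list (any backend).

    Hits are exactness/uniqueness-filtered first unless ``prefiltered``.
    """
    params = params or DetectionParams()
    if not prefiltered:
        hits = filter_hits(hits)
    by_read: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_read[h.read_id].append(h)
    calls = []
    n_chiastic = 0
    for read in reads:
        if read.length < params.min_read_len:
            continue
        candidates = pair_candidates(by_read.get(read.read_id, ()), read, params)
        chosen = best_candidate(candidates, read, params)
        if chosen is None:
            continue
        junction = resolve_junction(chosen, params)
        if junction is not None:
            calls.append(junction)
            n_chiastic += 1
    junctions = _merge_calls(calls)
    logger.info(
        "junction calling: %d/%d reads chiastic, %d distinct junctions",
        n_chiastic, len(reads), len(junctions),
    )
    return junctions


def detect_all(
    reads: Sequence[ReadRecord],
    genome: Mapping[str, GenomeSequence],
    params: DetectionParams | None = None,
) -> list[CircJunction]:
    """Full junction calling with the built-in exact aligner.

    Per read, the best passing candidate (maximal coverage, ties broken by
    the longer best segment; remaining ambiguity discards the read) is
    resolved; identical junctions are merged with their read sets unioned.
    """
    params = params or DetectionParams()
    index = ExactMatchIndex(genome, min_len=params.min_other_len)
    all_hits: list[AlignmentHit] = []
    for read in reads:
        if read.length < params.min_read_len:
            continue
        all_hits.extend(index.hits_for_read(read))
    return detect_from_hits(reads, all_hits, params)
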