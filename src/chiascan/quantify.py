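"""Circular vs total expression of circRNA loci across conditions.

For a circRNA and its host locus (e.g. an omega RNA adjoining an IS200/605
transposase gene), two disjoint read classes are counted in every
(condition, replicate) dataset:

* *junction reads* — chiastic reads whose resolved junction matches the
  ensemble within a small coordinate tolerance; they can only come from
  the circular isoform;
* *total reads* — reads aligning colinearly anywhere in the locus; they
  mix the linear isoform and circRNA body reads, but never junction reads.

Counts are normalized to reads per million (RPM) using each replicate's
library size, and summarized per condition as mean and standard error over
replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignmentHit, ExactMatchIndex, filter_hits
from .ensembles import CircEnsemble
from .io import AnnotationFeature, GenomeSequence, ReadRecord
from .junctions import CircJunction, DetectionParams, detect_all

logger = logging.getLogger(__name__)

_FLIP = {"+": "-", "-": "+", ".": "."}


@dataclass
class QuantDataset:
    """Alignments of one (condition, replicate) library, ready to count."""

    condition: str
    replicate: str
    junctions: list[CircJunction]
    colinear_hits: list[AlignmentHit]
    library_size: int


@dataclass(frozen=True)
class ExpressionRecord:
    locus_id: str
    ensemble_id: str
    condition: str
    replicate: str
    junction_count: int
    total_count: int
    library_size: int

    @property
    def junction_rpm(self) -> float:
        return self.junction_count / self.library_size * 1e6

    @property
    def total_rpm(self) -> float:
        return self.total_count / self.library_size * 1e6


@dataclass(frozen=True)
class ProfileSummary:
    locus_id: str
    condition: str
    series: str  # "circular" or "total"
    mean_rpm: float
    se_rpm: float
    n_replicates: int


def build_dataset(
    condition: str,
    replicate: str,
    reads: Sequence[ReadRecord],
    genome: Mapping[str, GenomeSequence],
    params: DetectionParams | None = None,
) -> QuantDataset:
    """Detect junctions and collect colinear hits for one library.

    A read is colinear when a single mismatch-free, uniquely placed hit
    covers at least ``min_read_cov`` of it; reads contributing a junction
    call are never colinear (the two classes are disjoint).  The library
    size is the number of reads after the minimum-length filter.
    """
    params = params or DetectionParams()
    junctions = detect_all(reads, genome, params)
    junction_reads: set[str] = set()
    for j in junctions:
        junction_reads |= j.read_ids
    index = ExactMatchIndex(genome, min_len=params.min_other_len)
    colinear: list[AlignmentHit] = []
    for read in reads:
        if read.length < params.min_read_len or read.read_id in junction_reads:
            continue
        hits = filter_hits(index.hits_for_read(read))
        for h in hits:
            if h.read_len >= params.min_read_cov * read.length:
                colinear.append(h)
    return QuantDataset(condition, replicate, junctions, colinear, len(reads))


def count_junction_reads(
    ensemble: CircEnsemble,
    dataset_junctions: Sequence[CircJunction],
    tol: int = 3,
) -> int:
    """Distinct reads of junctions matching the ensemble within +- tol."""
    reads: set[str] = set()
    for j in dataset_junctions:
        if (
            j.ref_id == ensemble.ref_id
            and j.strand == ensemble.strand
            and abs(j.start - ensemble.start) <= tol
            and abs(j.end - ensemble.end) <= tol
        ):
            reads |= j.read_ids
    return len(reads)


def count_total_reads(
    locus: AnnotationFeature,
    colinear_hits: Sequence[AlignmentHit],
    strand_specific: bool = True,
    invert_strand: bool = True,
) -> int:
    """Distinct colinear reads overlapping the locus by >= 1 bp."""
    reads: set[str] = set()
    for h in colinear_hits:
        if h.ref_id != locus.ref_id:
            continue
        if min(h.ref_end, locus.end) - max(h.ref_start, locus.start) < 1:
            continue
        if strand_specific and locus.strand in "+-":
            effective = _FLIP[h.strand] if invert_strand else h.strand
            if effective != locus.strand:
                continue
        reads.add(h.read_id)
    return len(reads)


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n)


def profile(
    locus: AnnotationFeature,
    ensemble: CircEnsemble,
    datasets: Sequence[QuantDataset],
    discovery_junctions: Sequence[CircJunction],
    tol: int = 3,
    min_reads: int = 10,
    strand_specific: bool = True,
    invert_strand: bool = True,
) -> tuple[list[ExpressionRecord], list[ProfileSummary]] | None:
    """Per-replicate expression records and per-condition summaries.

    Eligibility requires at least ``min_reads`` junction reads summed over
    the quantification datasets AND at least one junction read in the
    discovery (exonuclease-enriched) dataset; ineligible ensembles return
    None with the reason logged.
    """
    total_junction = sum(
        count_junction_reads(ensemble, ds.junctions, tol) for ds in datasets
    )
    discovery_support = count_junction_reads(ensemble, discovery_junctions, tol)
    if total_junction < min_reads:
        logger.info(
            "%s excluded: %d < %d junction reads in quantification data",
            ensemble.ensemble_id, total_junction, min_reads,
        )
        return None
    if discovery_support < 1:
        logger.info("%s excluded: no junction read in discovery data", ensemble.ensemble_id)
        return None

    locus_id = locus.name or f"{locus.ref_id}:{locus.start}-{locus.end}"
    records = [
        ExpressionRecord(
            locus_id=locus_id,
            ensemble_id=ensemble.ensemble_id,
            condition=ds.condition,
            replicate=ds.replicate,
            junction_count=count_junction_reads(ensemble, ds.junctions, tol),
            total_count=count_total_reads(
                locus, ds.colinear_hits, strand_specific, invert_strand
            ),
            library_size=ds.library_size,
        )
        for ds in datasets
    ]

    summaries = []
    conditions = sorted({r.condition for r in records})
    for condition in conditions:
        group = [r for r in records if r.condition == condition]
        for series, values in (
            ("circular", [r.junction_rpm for r in group]),
            ("total", [r.total_rpm for r in group]),
        ):
            mean, se = _mean_se(values)
            summaries.append(
                ProfileSummary(locus_id, condition, series, mean, se, len(group))
            )
    return records, summaries


def select_representative(
    candidates: Sequence[CircEnsemble],
    datasets: Sequence[QuantDataset],
    tol: int = 3,
) -> CircEnsemble:
    """The candidate with most junction reads over all datasets.

    Several ensembles can share one host locus; the representative is the
    one maximizing total junction-read support, ties broken by the smaller
    start coordinate.
    """
    if not candidates:
        raise ValueError("no candidate ensembles for locus")
    def sort_key(e: CircEnsemble):
        total = sum(count_junction_reads(e, ds.junctions, tol) for ds in datasets)
        return (-total, e.start, e.end)
    return min(candidates, key=sort_key)


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Long-format table of per-replicate expression records."""
    return pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in records],
            "ensemble_id": [r.ensemble_id for r in records],
            "condition": [r.condition for r in records],
            "replicate": [r.replicate for r in records],
            "junction_count": [r.junction_count for r in records],
            "total_count": [r.total_count for r in records],
            "library_size": [r.library_size for r in records],
            "junction_rpm": [r.junction_rpm for r in records],
            "total_rpm": [r.total_rpm for r in records],
        }
    )


def summaries_to_frame(summaries: Sequence[ProfileSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [s.locus_id for s in summaries],
            "condition": [s.condition for s in summaries],
            "series": [s.series for s in summaries],
            "mean_rpm": [s.mean_rpm for s in summaries],
            "se_rpm": [s.se_rpm for s in summaries],
            "n_replicates": [s.n_replicates for s in summaries],
        }
    )
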