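"""Annotation of circRNA ensembles against genome features.

Each ensemble is intersected with the annotation (any >= 1 bp overlap of
half-open intervals on the same replicon, strand-agnostic by default, since
antisense circRNAs are real calls in these data) and assigned a category by
a configurable feature-type priority.  Ensembles overlapping nothing are
"intergenic".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from .ensembles import CircEnsemble
from .io import AnnotationFeature

#: Default category precedence for multiply-annotated circRNAs.  The
#: annotation sources used in these organisms nest features (an omega RNA
#: inside a transposase gene inside an insertion sequence), so the order is
#: configuration, not hard-coded biology.
DEFAULT_PRIORITY: tuple[str, ...] = (
    "tRNA",
    "rRNA",
    "CDbox",
    "sRNA/omegaRNA",
    "SRP",
    "RNaseP",
    "IS",
    "CDS",
)

CATEGORIES = DEFAULT_PRIORITY + ("intergenic", "other")


def feature_category(feature_type: str) -> str:
    """Map an annotation feature type onto a circRNA category bucket."""
    ft = feature_type.lower()
    if "trna" in ft:
        return "tRNA"
    if "rrna" in ft:
        return "rRNA"
    if "cdbox" in ft or "c/d" in ft or "cd_box" in ft or "snorna" in ft:
        return "CDbox"
    if "srp" in ft or "signal_recognition" in ft:
        return "SRP"
    if "rnasep" in ft or "rnase_p" in ft:
        return "RNaseP"
    if "omega" in ft or "sotrna" in ft or ft in ("srna", "ncrna", "small_rna"):
        return "sRNA/omegaRNA"
    if ft.startswith("is") or "insertion" in ft or "transposase" in ft or "mobile" in ft:
        return "IS"
    if ft in ("cds", "gene", "mrna", "region", "protein_coding_gene"):
        return "CDS"
    warnings.warn(f"unknown feature type {feature_type!r}; bucketed as 'other'")
    return "other"


@dataclass
class CircAnnotation:
    """Feature overlaps and the assigned category of one ensemble."""

    ensemble_id: str
    overlaps: list[tuple[AnnotationFeature, int, bool]] = field(default_factory=list)
    category: str = "intergenic"


def intersect_features(
    ensembles: Sequence[CircEnsemble],
    features: Sequence[AnnotationFeature],
    same_strand_only: bool = False,
) -> list[CircAnnotation]:
    """Overlap every ensemble with the feature set via an interval index.

    An overlap is any >= 1 bp intersection of [start, end) intervals on the
    same ref_id.  ``same_strand`` is recorded per overlap; with
    ``same_strand_only`` opposite-strand overlaps are dropped entirely.
    """
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.ref_id, IntervalTree()).addi(f.start, f.end, f)
    annotations = []
    for e in ensembles:
        overlaps: list[tuple[AnnotationFeature, int, bool]] = []
        tree = trees.get(e.ref_id)
        if tree is not None:
            for iv in tree.overlap(e.start, e.end):
                f: AnnotationFeature = iv.data
                overlap_bp = min(e.end, f.end) - max(e.start, f.start)
                same_strand = f.strand == e.strand and f.strand in "+-"
                if same_strand_only and not same_strand:
                    continue
                overlaps.append((f, overlap_bp, same_strand))
        overlaps.sort(key=lambda t: (t[0].start, t[0].end, t[0].name, t[0].feature_type))
        annotations.append(CircAnnotation(ensemble_id=e.ensemble_id, overlaps=overlaps))
    return annotations


def categorize(
    annotation: CircAnnotation,
    priority: Sequence[str] | None = None,
) -> str:
    """Category of an ensemble: highest-priority overlapped feature class.

    Pure function of (overlaps, priority); empty overlaps mean
    "intergenic", overlaps of only unrecognized types mean "other".
    """
    priority = tuple(priority) if priority is not None else DEFAULT_PRIORITY
    if not annotation.overlaps:
        return "intergenic"
    present = {feature_category(f.feature_type) for f, _, _ in annotation.overlaps}
    for cat in priority:
        if cat in present:
            return cat
    return "other"


def annotate_ensembles(
    ensembles: Sequence[CircEnsemble],
    features: Sequence[AnnotationFeature],
    priority: Sequence[str] | None = None,
    same_strand_only: bool = False,
) -> list[CircAnnotation]:
    """Intersect and categorize in one pass."""
    annotations = intersect_features(ensembles, features, same_strand_only=same_strand_only)
    for ann in annotations:
        ann.category = categorize(ann, priority)
    return annotations


def write_annotation_table(
    ensembles: Sequence[CircEnsemble],
    annotations: Sequence[CircAnnotation],
    path,
) -> None:
    """TSV of annotated ensembles: coordinates, support, category, features."""
    by_id = {a.ensemble_id: a for a in annotations}
    with open(path, "w") as fh:
        fh.write(
            "ensemble_id\tref_id\tstart\tend\tstrand\tread_count"
            "\tsignificant\tcategory\tfeatures\n"
        )
        for e in ensembles:
            ann = by_id.get(e.ensemble_id, CircAnnotation(e.ensemble_id))
            names = ",".join(
                f.name or f.feature_type for f, _, _ in ann.overlaps
            )
            fh.write(
                f"{e.ensemble_id}\t{e.ref_id}\t{e.start}\t{e.end}\t{e.strand}"
                f"\t{e.read_count}\t{int(e.significant)}\t{ann.category}\t{names}\n"
            )
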