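"""Reading and writing the on-disk formats used by the pipeline.

Internal coordinates are 0-based, half-open, on the forward genome strand,
everywhere in the package.  Conversions to and from GFF3 (1-based inclusive)
and BED (0-based half-open) happen only inside this module, so coordinate
round trips are testable at the I/O boundary.

FASTQ qualities are discarded on input: the detection method operates on
sequence alone.  Paired-end mates are treated as independent reads; mate
files are simply concatenated into one read set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line

if TYPE_CHECKING:  # pragma: no cover
    from .junctions import CircJunction


@dataclass(frozen=True)
class GenomeSequence:
    """One reference replicon (chromosome or plasmid)."""

    ref_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (quality-free)."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationFeature:
    """A genome feature in internal 0-based half-open coordinates."""

    ref_id: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = "region"
    name: str = ""


def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Load a (multi-record) FASTA reference genome.

    Sequences are uppercased; ``N`` is allowed.  Duplicate record ids and
    empty files are errors.
    """
    path = Path(path)
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate reference id {rec.id!r} in {path}")
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def _sniff_read_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            first = line.lstrip()[0]
            if first == ">":
                return "fasta"
            if first == "@":
                return "fastq"
            raise ValueError(
                f"{path}: cannot determine read format from first record "
                f"character {first!r} (expected '>' or '@')"
            )
    raise ValueError(f"{path}: empty read file")


def load_reads(
    paths: Sequence[str | Path] | str | Path,
    min_read_len: int = 20,
) -> list[ReadRecord]:
    """Load and merge FASTA/FASTQ read files into one read set.

    Files are auto-detected per file.  Reads shorter than ``min_read_len``
    are dropped (a read of exactly ``min_read_len`` is kept).  Read-id
    collisions across merged files get a numeric suffix so ids stay unique
    after replicate merging.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    reads: list[ReadRecord] = []
    seen: set[str] = set()
    for path in paths:
        path = Path(path)
        fmt = _sniff_read_format(path)
        for rec in SeqIO.parse(str(path), fmt):
            seq = str(rec.seq).upper()
            if len(seq) < min_read_len:
                continue
            read_id = rec.id
            if read_id in seen:
                k = 2
                while f"{read_id}.{k}" in seen:
                    k += 1
                read_id = f"{read_id}.{k}"
            seen.add(read_id)
            reads.append(ReadRecord(read_id, seq))
    return reads


def _gff_feature_name(attributes) -> str:
    for key in ("Name", "ID", "locus_tag", "gene"):
        if key in attributes and attributes[key]:
            return attributes[key][0]
    return ""


def _read_gff(path: Path) -> list[AnnotationFeature]:
    features: list[AnnotationFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed row
                raise ValueError(f"{path}:{lineno}: bad GFF line ({exc})") from exc
            start, end = feat.start - 1, feat.end  # 1-based incl -> half-open
            if start >= end:
                warnings.warn(
                    f"{path}:{lineno}: skipping feature with empty interval "
                    f"({feat.start}, {feat.end})"
                )
                continue
            strand = feat.strand if feat.strand in "+-" else "."
            features.append(
                AnnotationFeature(
                    ref_id=feat.seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_type=feat.featuretype,
                    name=_gff_feature_name(feat.attributes),
                )
            )
    return features


def _read_bed(path: Path) -> list[AnnotationFeature]:
    features: list[AnnotationFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            if start >= end:
                warnings.warn(f"{path}:{lineno}: skipping empty BED interval")
                continue
            name = cols[3] if len(cols) > 3 and cols[3] else f"{cols[0]}:{start}-{end}"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            features.append(
                AnnotationFeature(
                    ref_id=cols[0],
                    start=start,
                    end=end,
                    strand=strand,
                    feature_type="region",
                    name=name,
                )
            )
    return features


def read_features(path: str | Path, fmt: str | None = None) -> list[AnnotationFeature]:
    """Load genome annotation from GFF3 or BED into internal coordinates.

    The format is taken from ``fmt`` (``"gff"`` or ``"bed"``) or, when
    omitted, guessed from the file extension.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "bed" if suffix == ".bed" else "gff"
    if fmt == "gff":
        return _read_gff(path)
    if fmt == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown feature format {fmt!r}")


def write_features_gff(features: Iterable[AnnotationFeature], path: str | Path) -> None:
    """Write features as GFF3 (internal half-open back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.name};Name={f.name}" if f.name else "."
            fh.write(
                f"{f.ref_id}\tchiascan\t{f.feature_type}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


def write_ensembles_bed(ensembles: Sequence, path: str | Path) -> None:
    """Write circRNA ensembles as BED6, sorted by (ref_id, start).

    Columns: ref_id, start, end, ensemble_id, read_count, strand.
    """
    with open(path, "w") as fh:
        fh.write("#ref_id\tstart\tend\tensemble_id\tread_count\tstrand\n")
        for e in sorted(ensembles, key=lambda e: (e.ref_id, e.start, e.end)):
            fh.write(
                f"{e.ref_id}\t{e.start}\t{e.end}\t{e.ensemble_id}"
                f"\t{e.read_count}\t{e.strand}\n"
            )


def write_junction_table(junctions: Sequence["CircJunction"], path: str | Path) -> None:
    """Write one row per supporting read of every circularization junction."""
    with open(path, "w") as fh:
        fh.write("read_id\tref_id\tstart\tend\tstrand\toverlap_len\tinserted_bases\n")
        for j in sorted(junctions, key=lambda j: (j.ref_id, j.start, j.end, j.strand)):
            for read_id in sorted(j.read_ids):
                overlap = j.read_detail.get(read_id, (0, 0))[0]
                fh.write(
                    f"{read_id}\t{j.ref_id}\t{j.start}\t{j.end}\t{j.strand}"
                    f"\t{overlap}\t{j.inserted_bases}\n"
                )


def read_junction_table(path: str | Path) -> list["CircJunction"]:
    """Read a junction table back into merged junction records."""
    from .junctions import CircJunction

    grouped: dict[tuple, CircJunction] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing junction-table header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            read_id, ref_id, start, end, strand, overlap, inserted = cols
            key = (ref_id, strand, int(start), int(end), inserted)
            if key not in grouped:
                grouped[key] = CircJunction(
                    ref_id=ref_id,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    read_ids=set(),
                    inserted_bases=inserted,
                )
            j = grouped[key]
            j.read_ids.add(read_id)
            j.read_detail[read_id] = (int(overlap), 0)
    return sorted(grouped.values(), key=lambda j: (j.ref_id, j.start, j.end, j.strand))
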