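"""Ungapped local alignment of reads to the genome.

Two backends produce the same hit records:

* a built-in exact aligner that enumerates every maximal exact match of a
  read against both strands of the genome (practical for the small genomes
  of prokaryotes and as a self-contained reference for testing), and
* a parser for the standard 12-column tabular report ("outfmt 6") written
  by an external local-alignment search tool, for large inputs.

All hits are reported in forward-genome coordinates; a minus-strand hit
means the read segment matches the reverse complement of the reference
interval.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import GenomeSequence, ReadRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_READ_CHARS = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped local alignment of a read segment to the genome.

    ``placements`` counts how many equally long, mismatch-free genome
    placements exist for the read segment ``[read_start, read_end)`` at its
    maximal match length; a uniquely aligned segment has ``placements == 1``.
    """

    read_id: str
    read_start: int
    read_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    mismatches: int = 0
    placements: int = 1

    @property
    def read_len(self) -> int:
        return self.read_end - self.read_start

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.ref_end - self.ref_start:
            raise ValueError("ungapped hit must have equal read and ref spans")


class ExactMatchIndex:
    """k-mer index over both strands of a genome for maximal-match lookup.

    The seed length equals ``min_len``, so every reported match is at least
    ``min_len`` long.  Seeds are extended to maximality; a match is emitted
    only from its leftmost seed, which makes the enumeration duplicate-free.
    """

    def __init__(self, genome: Mapping[str, GenomeSequence], min_len: int = 8):
        if min_len < 4:
            raise ValueError("min_len must be >= 4")
        self.min_len = min_len
        # oriented sequences: (ref_id, strand) -> sequence as the read sees it
        self._oriented: dict[tuple[str, str], str] = {}
        self._ref_len: dict[str, int] = {}
        self._index: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
        k = min_len
        for ref_id, rec in genome.items():
            self._ref_len[ref_id] = rec.length
            for strand, oseq in (("+", rec.sequence), ("-", revcomp(rec.sequence))):
                self._oriented[(ref_id, strand)] = oseq
                for j in range(len(oseq) - k + 1):
                    kmer = oseq[j : j + k]
                    if "N" in kmer:
                        continue
                    self._index[kmer].append((ref_id, strand, j))

    def hits_for_read(self, read: ReadRecord) -> list[AlignmentHit]:
        seq = read.sequence
        if set(seq) - _VALID_READ_CHARS:
            bad = sorted(set(seq) - _VALID_READ_CHARS)
            raise ValueError(f"read {read.read_id!r} contains non-ACGTN bases {bad}")
        k = self.min_len
        raw: list[tuple[int, int, str, str, int]] = []  # read_start, len, ref, strand, opos
        n = len(seq)
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            for ref_id, strand, j in self._index.get(kmer, ()):
                oseq = self._oriented[(ref_id, strand)]
                # left-maximality: this match is found from its leftmost seed only
                if i > 0 and j > 0 and seq[i - 1] == oseq[j - 1] and seq[i - 1] != "N":
                    continue
                x, y = i + k, j + k
                m = len(oseq)
                while x < n and y < m and seq[x] == oseq[y] and seq[x] != "N":
                    x += 1
                    y += 1
                raw.append((i, x - i, ref_id, strand, j))
        # placements per distinct read segment at its maximal length
        seg_counts: dict[tuple[int, int], int] = defaultdict(int)
        for i, length, *_ in raw:
            seg_counts[(i, i + length)] += 1
        hits = []
        for i, length, ref_id, strand, j in raw:
            if strand == "+":
                ref_start, ref_end = j, j + length
            else:
                ref_len = self._ref_len[ref_id]
                ref_start, ref_end = ref_len - (j + length), ref_len - j
            hits.append(
                AlignmentHit(
                    read_id=read.read_id,
                    read_start=i,
                    read_end=i + length,
                    ref_id=ref_id,
                    ref_start=ref_start,
                    ref_end=ref_end,
                    strand=strand,
                    mismatches=0,
                    placements=seg_counts[(i, i + length)],
                )
            )
        hits.sort(key=lambda h: (h.read_start, h.read_end, h.ref_id, h.ref_start, h.strand))
        return hits


def enumerate_exact_hits(
    read: ReadRecord,
    genome: Mapping[str, GenomeSequence],
    min_len: int = 8,
    index: ExactMatchIndex | None = None,
) -> list[AlignmentHit]:
    """Every maximal exact match of the read (length >= ``min_len``).

    Matches are enumerated against both strands of every genome record and
    reported in forward-genome coordinates.  ``index`` may be a prebuilt
    :class:`ExactMatchIndex` to amortize indexing over many reads.
    """
    if index is None:
        index = ExactMatchIndex(genome, min_len=min_len)
    elif index.min_len != min_len:
        raise ValueError("prebuilt index has a different min_len")
    return index.hits_for_read(read)


def parse_tabular_hits(
    path: str | Path,
    reads: Iterable[ReadRecord] | Mapping[str, ReadRecord],
) -> list[AlignmentHit]:
    """Parse a standard 12-column tabular alignment report into hits.

    Columns: query id, subject id, % identity, alignment length, mismatches,
    gap opens, q.start, q.end, s.start, s.end, e-value, bit score.  Query
    coordinates are 1-based inclusive; a subject start greater than subject
    end encodes a minus-strand hit.  Rows with gap opens are discarded
    (the pipeline is strictly ungapped); rows for unknown read ids are
    skipped with a warning.
    """
    if isinstance(reads, Mapping):
        read_ids = set(reads)
    else:
        read_ids = {r.read_id for r in reads}
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 tab-separated columns")
            try:
                qid, sid = cols[0], cols[1]
                length = int(cols[3])
                mismatches = int(cols[4])
                gapopen = int(cols[5])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if qid not in read_ids:
                warnings.warn(f"{path}:{lineno}: read id {qid!r} not in read set; row skipped")
                continue
            if gapopen > 0:
                continue
            read_start, read_end = qstart - 1, qend
            if sstart <= send:
                strand, ref_start, ref_end = "+", sstart - 1, send
            else:
                strand, ref_start, ref_end = "-", send - 1, sstart
            if read_end - read_start != ref_end - ref_start or read_end - read_start != length:
                raise ValueError(f"{path}:{lineno}: inconsistent ungapped coordinates")
            rows.append((qid, read_start, read_end, sid, ref_start, ref_end, strand, mismatches))
    exact_counts: dict[tuple[str, int, int], int] = defaultdict(int)
    for qid, rs, re_, *_rest, mm in rows:
        if mm == 0:
            exact_counts[(qid, rs, re_)] += 1
    hits = []
    for qid, rs, re_, sid, fs, fe, strand, mm in rows:
        placements = max(1, exact_counts.get((qid, rs, re_), 0))
        hits.append(
            AlignmentHit(
                read_id=qid,
                read_start=rs,
                read_end=re_,
                ref_id=sid,
                ref_start=fs,
                ref_end=fe,
                strand=strand,
                mismatches=mm,
                placements=placements,
            )
        )
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    require_unique: bool = True,
    require_exact: bool = True,
) -> list[AlignmentHit]:
    """Keep mismatch-free, uniquely placed hits (the junction-calling filter)."""
    kept = []
    for h in hits:
        if require_exact and h.mismatches != 0:
            continue
        if require_unique and h.placements != 1:
            continue
        kept.append(h)
    return kept


def run_blastn_short(
    genome_fasta: str | Path,
    reads_fasta: str | Path,
    out_path: str | Path,
    evalue: float = 1000.0,
    extra_args: Sequence[str] = (),
) -> Path:
    """Run an external BLASTn short-sequence, ungapped search to outfmt 6.

    Convenience wrapper; the parameters are passed through verbatim and the
    contract downstream is only on the tabular report.  Requires the
    ``makeblastdb`` and ``blastn`` executables on PATH.
    """
    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("blastn/makeblastdb not found on PATH")
    out_path = Path(out_path)
    with tempfile.TemporaryDirectory() as tmp:
        db = Path(tmp) / "genome_db"
        subprocess.run(
            ["makeblastdb", "-in", str(genome_fasta), "-dbtype", "nucl", "-out", str(db)],
            check=True,
            capture_output=True,
        )
        cmd = [
            "blastn",
            "-task", "blastn-short",
            "-ungapped",
            "-dust", "no",
            "-evalue", str(evalue),
            "-query", str(reads_fasta),
            "-db", str(db),
            "-outfmt", "6",
            "-out", str(out_path),
            *extra_args,
        ]
        subprocess.run(cmd, check=True, capture_output=True)
    return out_path
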