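"""Synthetic genomes, planted circRNAs, and junction-spanning reads.

The generator emulates the statistical structure of an exonuclease-enriched
(RNase R) circRNA-Seq library from a small prokaryotic genome: a random
reference sequence, a set of planted circRNA intervals, reads crossing each
circle's junction (prefix from the circle's 3' end, suffix from its 5'
start, optionally separated by untemplated inserted bases such as the
post-maturation tRNA "CCA"), and colinear background reads.

Two idealizations make planted truth exactly recoverable by the detection
filters, and are deliberate:

* circle placements are rejection-sampled so the junction-flanking 8-mers
  are unique in the genome (both strands) — the uniqueness filter then
  provably keeps planted junction reads; real repetitive elements violate
  this, and that failure mode is exercised separately with duplicated
  flanks;
* placements where the genome sequence continues across the junction by
  chance (which would shift the maximal alignment by a base or two) are
  rejected, so resolved coordinates equal planted coordinates exactly
  rather than within the grouping tolerance.

All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import revcomp
from .io import (
    AnnotationFeature,
    GenomeSequence,
    ReadRecord,
    write_features_gff,
)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``reads_per_circ`` is a single count or one count per circle.
    ``protocol_inverted`` emulates dUTP-type stranded kits where the
    sequenced read is antisense to the transcript; detection with
    ``invert_strand=True`` then recovers the transcript strand.
    ``per_read_error_rate`` is the fraction of reads receiving a single
    substitution at a uniform position.
    """

    genome_len: int = 100_000
    n_circ: int = 20
    circ_size_range: tuple[int, int] = (100, 3500)
    reads_per_circ: int | Sequence[int] = 15
    read_len: int = 40
    background_reads: int = 5000
    insert_junction_bases: str = ""
    per_read_error_rate: float = 0.0
    fraction_minus_strand: float = 0.5
    protocol_inverted: bool = True
    min_other_len: int = 8
    seed: int = 0
    ref_id: str = "chrSim"

    def __post_init__(self) -> None:
        if self.genome_len < 1000:
            raise ValueError("genome_len must be >= 1000")
        lo, hi = self.circ_size_range
        if not (self.read_len < lo <= hi):
            raise ValueError("circle sizes must lie in (read_len, max]")
        if not (0.0 <= self.per_read_error_rate <= 1.0):
            raise ValueError("per_read_error_rate must be in [0, 1]")
        core = self.read_len - len(self.insert_junction_bases)
        if core < 2 * self.min_other_len:
            raise ValueError("read_len too short for two segments of min_other_len")

    def reads_for_circle(self, i: int) -> int:
        if isinstance(self.reads_per_circ, int):
            return self.reads_per_circ
        return self.reads_per_circ[i]


@dataclass
class TruthRecord:
    """Ground truth for one planted circRNA.

    ``inserted_bases`` is the untemplated junction sequence in transcript
    orientation; ``read_space_insert`` is the same sequence as it appears
    in the emitted reads (reverse-complemented under an inverted protocol),
    which is what junction calling reports verbatim.
    """

    circ_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    inserted_bases: str = ""
    read_space_insert: str = ""
    n_junction_reads_emitted: int = 0


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenomeSequence:
    """An i.i.d. uniform A/C/G/T genome, deterministic under the seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    idx = rng.integers(0, 4, size=config.genome_len)
    seq = "".join(_BASES[i] for i in idx)
    return GenomeSequence(config.ref_id, seq)


def _count_occurrences(haystack: str, needle: str) -> int:
    count = 0
    pos = haystack.find(needle)
    while pos != -1:
        count += 1
        pos = haystack.find(needle, pos + 1)
    return count


def _flanks_unique(genome_seq: str, genome_rc: str, start: int, end: int, k: int) -> bool:
    """Both junction-flanking k-mers occur exactly once across both strands."""
    for kmer in (genome_seq[start : start + k], genome_seq[end - k : end]):
        if _count_occurrences(genome_seq, kmer) + _count_occurrences(genome_rc, kmer) != 1:
            return False
    return True


def _junction_extendable(genome_seq: str, start: int, end: int, ins: str) -> bool:
    """Would a maximal exact match slide across the planted junction?

    Checks alignment extension on both read strands: the genome base just
    outside either circle boundary must not equal the adjacent junction
    base of the read (or its complement, for reads sequenced from the
    opposite strand).
    """
    nxt = ins[0] if ins else genome_seq[start]  # read base after the prefix segment
    prv = ins[-1] if ins else genome_seq[end - 1]  # read base before the suffix segment
    if genome_seq[end] == nxt or genome_seq[start - 1] == prv:
        return True
    if ins and (genome_seq[start - 1] == _COMP[ins[0]] or genome_seq[end] == _COMP[ins[-1]]):
        return True
    return False


def plant_circles(
    genome: GenomeSequence,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_tries: int = 200_000,
) -> list[TruthRecord]:
    """Rejection-sample disjoint circRNA intervals with unique flanks."""
    k = config.min_other_len
    seq = genome.sequence
    seq_rc = revcomp(seq)
    lo, hi = config.circ_size_range
    placed: list[tuple[int, int]] = []
    truths: list[TruthRecord] = []
    tries = 0
    while len(truths) < config.n_circ:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_circ} circles after {max_tries} tries; "
                "try a larger genome or fewer/smaller circles"
            )
        size = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1, genome.length - size - 1))
        end = start + size
        if any(start < e and s < end for s, e in placed):
            continue
        if _junction_extendable(seq, start, end, config.insert_junction_bases):
            continue
        if not _flanks_unique(seq, seq_rc, start, end, k):
            continue
        strand = "-" if rng.random() < config.fraction_minus_strand else "+"
        placed.append((start, end))
        truths.append(
            TruthRecord(
                circ_id=f"truth_{len(truths):03d}",
                ref_id=genome.ref_id,
                start=start,
                end=end,
                strand=strand,
            )
        )
    truths.sort(key=lambda t: t.start)
    for i, t in enumerate(truths):
        t.circ_id = f"truth_{i:03d}"
    return truths


def _substitute(seq: str, pos: int, rng: np.random.Generator) -> str:
    old = seq[pos]
    choices = [b for b in _BASES if b != old]
    new = choices[int(rng.integers(0, 3))]
    return seq[:pos] + new + seq[pos + 1 :]


def emit_reads(
    genome: GenomeSequence,
    truths: Sequence[TruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ReadRecord]:
    """Junction-spanning reads per circle plus colinear background reads.

    A junction read in transcript orientation is the circle's last ``a``
    transcript bases, the inserted junction bases, then its first ``b``
    bases (``a + len(insert) + b == read_len``, both segments at least
    ``min_other_len``).  Under an inverted protocol the emitted read is the
    reverse complement.  Truth records are updated in place with emitted
    junction-read counts and the read-space insert.
    """
    seq = genome.sequence
    ins = config.insert_junction_bases
    core = config.read_len - len(ins)
    reads: list[ReadRecord] = []
    for i, truth in enumerate(truths):
        n = config.reads_for_circle(i)
        s, e = truth.start, truth.end
        for r in range(n):
            a = int(rng.integers(config.min_other_len, core - config.min_other_len + 1))
            b = core - a
            if truth.strand == "+":
                transcript_read = seq[e - a : e] + ins + seq[s : s + b]
            else:
                transcript_read = revcomp(seq[s : s + a]) + ins + revcomp(seq[e - b : e])
            read_seq = revcomp(transcript_read) if config.protocol_inverted else transcript_read
            if config.per_read_error_rate > 0 and rng.random() < config.per_read_error_rate:
                read_seq = _substitute(read_seq, int(rng.integers(0, len(read_seq))), rng)
            reads.append(ReadRecord(f"{truth.circ_id}_read{r:03d}", read_seq))
        truth.n_junction_reads_emitted = n
        truth.inserted_bases = ins
        truth.read_space_insert = revcomp(ins) if config.protocol_inverted else ins
    for kbg in range(config.background_reads):
        pos = int(rng.integers(0, genome.length - config.read_len + 1))
        read_seq = seq[pos : pos + config.read_len]
        if rng.random() < 0.5:
            read_seq = revcomp(read_seq)
        if config.per_read_error_rate > 0 and rng.random() < config.per_read_error_rate:
            read_seq = _substitute(read_seq, int(rng.integers(0, len(read_seq))), rng)
        reads.append(ReadRecord(f"bg_{kbg:05d}", read_seq))
    return reads


@dataclass
class SimulatedDataset:
    genome: GenomeSequence
    reads: list[ReadRecord]
    truths: list[TruthRecord]
    config: SimulationConfig

    @property
    def truth_features(self) -> list[AnnotationFeature]:
        """Planted circles as gene features, for annotation tests."""
        return [
            AnnotationFeature(
                ref_id=t.ref_id,
                start=t.start,
                end=t.end,
                strand=t.strand,
                feature_type="gene",
                name=t.circ_id,
            )
            for t in self.truths
        ]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genome + planted circles + reads, all from the single config seed."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    truths = plant_circles(genome, config, rng)
    reads = emit_reads(genome, truths, config, rng)
    return SimulatedDataset(genome, reads, truths, config)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, reads FASTA, truth TSV/BED, and a truth GFF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "reads": out_dir / "reads.fa",
        "truth_tsv": out_dir / "truth.tsv",
        "truth_bed": out_dir / "truth.bed",
        "truth_gff": out_dir / "truth_genes.gff",
    }
    with open(paths["genome"], "w") as fh:
        fh.write(f">{dataset.genome.ref_id}\n")
        seq = dataset.genome.sequence
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    with open(paths["reads"], "w") as fh:
        for read in dataset.reads:
            fh.write(f">{read.read_id}\n{read.sequence}\n")
    with open(paths["truth_tsv"], "w") as fh:
        fh.write(
            "circ_id\tref_id\tstart\tend\tstrand\tn_junction_reads"
            "\tinserted_bases\tread_space_insert\n"
        )
        for t in dataset.truths:
            fh.write(
                f"{t.circ_id}\t{t.ref_id}\t{t.start}\t{t.end}\t{t.strand}"
                f"\t{t.n_junction_reads_emitted}\t{t.inserted_bases}\t{t.read_space_insert}\n"
            )
    with open(paths["truth_bed"], "w") as fh:
        fh.write("#ref_id\tstart\tend\tcirc_id\tn_reads\tstrand\n")
        for t in dataset.truths:
            fh.write(
                f"{t.ref_id}\t{t.start}\t{t.end}\t{t.circ_id}"
                f"\t{t.n_junction_reads_emitted}\t{t.strand}\n"
            )
    write_features_gff(dataset.truth_features, paths["truth_gff"])
    return paths
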