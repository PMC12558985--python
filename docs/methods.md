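# Methods

## Detection model

`chiascan` treats circRNA discovery as a geometry problem on ungapped
local alignments.  A read of length *L* crossing a circularization
junction decomposes into a 5′ segment drawn from the transcript's 3′ end
and a 3′ segment drawn from its 5′ start; on the genome the two segments
therefore appear in swapped order (chiastic).  All coordinates are 0-based
half-open on the forward genome strand; conversions to GFF3 (1-based
inclusive) and BED happen only at I/O boundaries, so coordinate round
trips are exactly testable.

Alignments come from one of two backends with an identical hit contract:

* **built-in** — every maximal exact match (length ≥ 8 nt, both strands)
  of the read, enumerated from a k-mer index with left-maximal seeding, so
  each maximal match is found exactly once;
* **tabular** — a standard 12-column report from an external ungapped
  local search tool.  Rows with gap opens are discarded; minus-strand hits
  (subject start > end) are normalized into ascending forward coordinates.

A segment is *uniquely placed* when the number of mismatch-free genome
placements of the exact read interval at its maximal match length is one.
Exactness is applied before uniqueness; uniqueness is then evaluated on
the surviving mismatch-free placements.  This is the strictest reading of
"uniquely aligned" and is deterministic.

### Junction filters

A candidate is an ordered chiastic pair of filtered hits on one replicon
and strand with at most `max_overlap` shared or `max_gap` uncovered read
bases at the junction.  It passes when

1. union read coverage ≥ `min_read_cov` (overlapping bases counted once —
   the conservative reading of "together cover");
2. the longer segment ≥ `min_best_fraction · L` (real-valued comparison,
   no rounding);
3. the shorter segment ≥ `min_other_len`;
4. resolved span `end − start` ≤ `max_span` (the span *is* the circle
   size).

Failures report the first violated rule in that order.  Gap bases —
read sequence claimed by neither segment — are carried through verbatim as
`inserted_bases`; untemplated "CCA" inside a junction is the signature of
a whole circular tRNA circularized after 3′ maturation.

### Coordinate resolution and strand

On strand "+": `start = suffix.ref_start + overlap`,
`end = prefix.ref_end`; on strand "−": `start = prefix.ref_start`,
`end = suffix.ref_end − overlap`.  Ambiguous (overlapping) junction bases
are thus kept by the read-prefix segment — the transcript's 3′ side — and
trimmed from the suffix.  Any consistent trimming rule differs by at most
`max_overlap` = 3 nt and is absorbed by the grouping tolerance; this one is
fixed so outputs are deterministic.  A resolution with `start ≥ end` is
degenerate and discarded (defensive only: it cannot arise while
`min_other_len > max_overlap`).

With `invert_strand` (default, matching dUTP-type stranded kits that
sequence the antisense strand) the reported strand is the read strand
flipped; `strand_specific=False` collapses everything to "." before
grouping, for unstranded protocols.

### Per-read selection

If several candidates of one read pass, the one with maximal coverage
wins, ties broken by the longer best segment.  Remaining ties that resolve
to *different* junctions discard the read as ambiguous (counting one
arbitrarily would be order-dependent); ties resolving to the *same*
junction keep one, since they are the same call.  A read therefore
supports at most one junction.

## Ensembles

Within each (replicon, strand), junctions are sorted by (start, end) and
clustered single-linkage under |Δstart| ≤ `group_tol` AND |Δend| ≤
`group_tol`.  Single linkage makes the pairwise rule transitive and
order-independent; the price is that a chained cluster's diameter can
exceed `group_tol`, which is intended (ragged 5S-type junction clouds stay
one circRNA).  Ensemble coordinates are min start / max end over members —
the widest genomic extent, equivalently min/max in transcript orientation
on either strand.  An ensemble is significant with ≥ `min_reads` distinct
supporting reads (boundary inclusive).

## Annotation

Overlap is any ≥ 1 bp intersection of half-open intervals on the same
replicon, strand-agnostic by default because antisense circRNAs are real
calls (e.g. a circle exactly antisense to a circular tRNA intron); a
`same_strand` flag restricts it.  The category of a multiply-annotated
circle follows a configurable priority, default
tRNA > rRNA > CDbox > sRNA/ωRNA > SRP > RNaseP > IS > CDS, chosen so the
most specific nested feature wins (an ωRNA inside a transposase gene
inside an IS annotation is categorized by the ωRNA).  This is
configuration, not hard-coded biology.  No overlap means intergenic;
unrecognized feature types fall into an "other" bucket with a warning.

## Quantification

For a host locus and its circRNA ensemble, each (condition, replicate)
library contributes two disjoint read classes: *junction reads* (junction
calls matching the ensemble within ± `group_tol` at both coordinates, same
replicon and strand) and *total reads* (reads with a unique mismatch-free
colinear hit covering ≥ `min_read_cov` of the read and overlapping the
locus by ≥ 1 bp; junction-supporting reads are excluded by construction).
`RPM = count / library_size × 10⁶`, where library size is the number of
reads after the minimum-length filter (a flag in `build_dataset` callers
can substitute raw counts).  Per condition, mean and standard error over
replicates use the sample standard deviation (n − 1); SE is 0 for a single
replicate.  An ensemble is profiled only if it has ≥ `min_reads` junction
reads summed over the quantification libraries and ≥ 1 junction read in
the discovery (exonuclease-enriched) data.  When several ensembles share a
locus the representative is the one with most junction reads over all
libraries, ties to the smaller start coordinate.

## Parameters

| name | default | unit | role |
|---|---|---|---|
| `max_span` | 3500 | nt | maximum circle size |
| `min_read_cov` | 0.90 | fraction | union coverage of both segments |
| `min_best_fraction` | 0.50 | fraction | best-segment coverage |
| `min_other_len` | 8 | nt | secondary-segment length |
| `max_overlap` / `max_gap` | 3 / 3 | nt | junction slack |
| `group_tol` | 3 | nt | ensemble clustering / dataset matching |
| `min_reads` | 10 | reads | significance threshold |
| `invert_strand` | on | — | dUTP-type stranded protocols |
| `min_read_len` | 20 | nt | read length floor |

A bare run uses exactly these values; every effective value is snapshotted
to `params.json` by the `run` subcommand.

## Synthetic data

The generator emulates an RNase-R-enriched small-RNA library from a small
prokaryotic genome: an i.i.d. uniform A/C/G/T reference, disjoint planted
circle intervals with uniform sizes, junction reads built as
`genome[end−a, end) + insert + genome[start, start+b)` (reverse-
complemented per circle strand and protocol inversion) with both segments
≥ 8 nt, and colinear background reads from both strands.  The error model
is a single uniform substitution in a configurable fraction of reads —
indels are deliberately excluded because the detector's rejection rule is
mismatch-based and indels would conflate with the junction gap
bookkeeping.

Two rejection-sampling rules make planted truth a theorem rather than a
probabilistic claim: junction-flanking 8-mers must be unique in the genome
across both strands (so the uniqueness filter provably keeps planted
reads), and the genome may not continue across the junction by chance (so
maximal matches cannot slide and resolved coordinates equal planted
coordinates exactly).  Real genomes violate both — IS elements are
repetitive, and one-base junction slippage is common — so passing the
exact-recovery tests shows the machinery is correct, not that real-data
recovery is exact; the repetitive failure mode is exercised separately by
duplicating a planted flank and asserting those reads are dropped.  What
the generator does **not** model: platform-specific error profiles, indels,
rolling-circle multi-wrap reads, RNase R efficiency beyond read counts,
coverage biases, and adapters.

Problem sizes in the test suite and acceptance script (a 100 kb genome
with 20 circles and ~5300 reads; ten 20 kb genomes for the oracle
cross-check; 12-replicate expression designs on 20 kb genomes) were chosen
as the smallest scales at which every contract — including the
significance boundary and replicate statistics — is still exercised.

## Verification strategy

The detection path is cross-checked against two independently written
brute-force oracles (`tests/_oracle.py`): a split-point enumeration oracle
that tests exact genome occurrence of both read parts by direct string
search (used for error-free reads, where every junction is a clean
two-part split), and an exhaustive oracle that enumerates *all* maximal
exact matches by numpy diagonal-run dynamic programming with no seeding
(used for erroneous reads, whose junction candidates can involve interior
read segments that no single split expresses).  The external-aligner route
is checked against the built-in aligner end to end on a BLASTN report.
Interval-index annotation is checked against a quadratic all-pairs scan.

## Known limitations

* Circles shorter than the read (rolling-circle, multi-wrap reads) are out
  of scope; the chiastic test uses strict ref-start inequality.
* Junctions spanning two genome records are not called.
* Junction calling is mismatch-intolerant by design; a substitution inside
  either segment drops the read, so support counts are conservative under
  high error rates.  A substitution in the outermost read bases (outside
  both segments) can still pass the 90 % coverage rule; such reads
  occasionally produce single-read spurious calls, which the ≥ 10-read
  significance threshold removes.
* The built-in aligner is designed for genomes of prokaryotic size
  (megabases); large eukaryotic genomes should use the tabular backend
  with an external search tool.
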