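"""Independent brute-force oracles for cross-checking the pipeline.

Everything here works by direct string scanning and exhaustive
enumeration — no k-mer index, no hit pairing, no interval tree — so it can
serve as an independent reference for the main implementation.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _occurrences(haystack: str, needle: str) -> list[int]:
    out = []
    pos = haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


_FLIP = {"+": "-", "-": "+", ".": "."}


def oracle_detect_keys(reads, genome: Mapping, params) -> set[tuple]:
    """Brute-force split-enumeration junction calling.

    For every read it tries every split (k1, k2) with both parts at least
    ``min_other_len`` long and at most ``max_overlap`` shared /
    ``max_gap`` skipped junction bases, tests exact genome occurrence of
    both parts on both strands by direct string search, and applies the
    same uniqueness, coverage, best-segment, and span filters plus the same
    per-read best-candidate selection as the caller.  Occurrences are
    counted at maximal extension relative to the read (an occurrence whose
    flanking genome base continues the read belongs to a longer segment),
    matching the caller's definition of a uniquely placed segment.

    Returns the set of (ref_id, strand, start, end, inserted_bases) keys.
    """
    oriented: dict[tuple[str, str], str] = {}
    ref_len: dict[str, int] = {}
    for ref_id, rec in genome.items():
        oriented[(ref_id, "+")] = rec.sequence
        oriented[(ref_id, "-")] = _rc(rec.sequence)
        ref_len[ref_id] = rec.length

    keys: set[tuple] = set()
    for read in reads:
        seq = read.sequence
        L = len(seq)
        if L < params.min_read_len:
            continue
        candidates = []  # (coverage, best_len, key)
        for k1 in range(params.min_other_len, L - params.min_other_len + 1):
            k2_lo = max(1, k1 - params.max_overlap)
            k2_hi = min(L - params.min_other_len, k1 + params.max_gap)
            for k2 in range(k2_lo, k2_hi + 1):
                prefix, suffix = seq[:k1], seq[k2:]
                overlap = max(0, k1 - k2)
                gap = max(0, k2 - k1)
                inserted = seq[k1:k2] if k2 > k1 else ""
                # maximal occurrences of each part, per oriented genome
                pre_occ: dict[tuple[str, str], list[int]] = {}
                suf_occ: dict[tuple[str, str], list[int]] = {}
                n_pre = n_suf = 0
                for key_g, oseq in oriented.items():
                    pre = [
                        o for o in _occurrences(oseq, prefix)
                        if k1 == L or o + k1 == len(oseq) or oseq[o + k1] != seq[k1]
                    ]
                    suf = [
                        o for o in _occurrences(oseq, suffix)
                        if o == 0 or oseq[o - 1] != seq[k2 - 1]
                    ]
                    pre_occ[key_g], suf_occ[key_g] = pre, suf
                    n_pre += len(pre)
                    n_suf += len(suf)
                if n_pre != 1 or n_suf != 1:
                    continue  # uniqueness filter
                for (ref_id, strand), pre in pre_occ.items():
                    for op in pre:
                        for os_ in suf_occ[(ref_id, strand)]:
                            if strand == "+":
                                p_start, p_end = op, op + k1
                                s_start, s_end = os_, os_ + (L - k2)
                            else:
                                n_ref = ref_len[ref_id]
                                p_start, p_end = n_ref - (op + k1), n_ref - op
                                s_start = n_ref - (os_ + (L - k2))
                                s_end = n_ref - os_
                            chiastic = (
                                s_start < p_start if strand == "+" else s_start > p_start
                            )
                            if not chiastic:
                                continue
                            coverage = (k1 + (L - k2) - overlap) / L
                            best = max(k1, L - k2)
                            if coverage < params.min_read_cov:
                                continue
                            if best < params.min_best_fraction * L:
                                continue
                            if strand == "+":
                                start, end = s_start + overlap, p_end
                            else:
                                start, end = p_start, s_end - overlap
                            if start >= end or end - start > params.max_span:
                                continue
                            out_strand = _FLIP[strand] if params.invert_strand else strand
                            if not params.strand_specific:
                                out_strand = "."
                            candidates.append(
                                (coverage, best, (ref_id, out_strand, start, end, inserted))
                            )
        if not candidates:
            continue
        best_score = max((c, b) for c, b, _ in candidates)
        tied = {key for c, b, key in candidates if (c, b) == best_score}
        if len(tied) == 1:
            keys.add(tied.pop())
    return keys


def dp_maximal_matches(read_seq: str, genome: Mapping, min_len: int) -> set[tuple]:
    """All maximal exact matches via exhaustive diagonal-run dynamic programming.

    Builds the full read-vs-genome match matrix row by row (numpy) and reads
    off every diagonal run of length >= ``min_len`` that cannot be extended;
    no seeding or indexing involved.  Same tuple format as
    :func:`brute_force_maximal_matches`.
    """
    out = set()
    r = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    L = len(r)
    n_code = ord("N")
    for ref_id, rec in genome.items():
        for strand, oseq in (("+", rec.sequence), ("-", _rc(rec.sequence))):
            g = np.frombuffer(oseq.encode(), dtype=np.uint8)
            G = len(g)
            prev = np.zeros(G, dtype=np.int32)
            for i in range(L):
                m = (g == r[i]) & (g != n_code)
                cur = np.zeros(G, dtype=np.int32)
                cur[0] = 1 if m[0] else 0
                cur[1:] = np.where(m[1:], prev[:-1] + 1, 0)
                if i + 1 < L:
                    cont = np.zeros(G, dtype=bool)
                    cont[:-1] = (g[1:] == r[i + 1]) & (g[1:] != n_code)
                else:
                    cont = np.zeros(G, dtype=bool)
                ends = (cur >= min_len) & ~cont
                for j in np.nonzero(ends)[0]:
                    length = int(cur[j])
                    i0, j0 = i - length + 1, int(j) - length + 1
                    if strand == "+":
                        rs, re_ = j0, j0 + length
                    else:
                        rs, re_ = rec.length - (j0 + length), rec.length - j0
                    out.add((i0, i0 + length, ref_id, rs, re_, strand))
                prev = cur
    return out


def oracle_detect_keys_exhaustive(reads, genome: Mapping, params) -> set[tuple]:
    """Junction calling on top of the exhaustive DP match enumeration.

    The split-point oracle above cannot represent candidates whose segments
    are interior read intervals (which arise next to sequencing errors), so
    for reads with errors this completes it: every maximal match from
    :func:`dp_maximal_matches` is paired by independently written chiastic /
    tolerance / coverage / uniqueness / span logic and the same per-read
    selection.  Returns (ref_id, strand, start, end, inserted_bases) keys.
    """
    keys: set[tuple] = set()
    for read in reads:
        seq = read.sequence
        L = len(seq)
        if L < params.min_read_len:
            continue
        matches = sorted(dp_maximal_matches(seq, genome, params.min_other_len))
        placement_counts: dict[tuple[int, int], int] = defaultdict(int)
        for rs, re_, *_ in matches:
            placement_counts[(rs, re_)] += 1
        unique = [m for m in matches if placement_counts[(m[0], m[1])] == 1]
        candidates = []
        for p in unique:
            for s in unique:
                p_rs, p_re, p_ref, p_fs, p_fe, p_strand = p
                s_rs, s_re, s_ref, s_fs, s_fe, s_strand = s
                if p_ref != s_ref or p_strand != s_strand:
                    continue
                if not (p_rs < s_rs and p_re < s_re):
                    continue
                overlap = max(0, p_re - s_rs)
                gap = max(0, s_rs - p_re)
                if overlap > params.max_overlap or gap > params.max_gap:
                    continue
                chiastic = s_fs < p_fs if p_strand == "+" else s_fs > p_fs
                if not chiastic:
                    continue
                p_len, s_len = p_re - p_rs, s_re - s_rs
                coverage = (p_len + s_len - overlap) / L
                best = max(p_len, s_len)
                if coverage < params.min_read_cov:
                    continue
                if best < params.min_best_fraction * L:
                    continue
                if min(p_len, s_len) < params.min_other_len:
                    continue
                if p_strand == "+":
                    start, end = s_fs + overlap, p_fe
                else:
                    start, end = p_fs, s_fe - overlap
                if start >= end or end - start > params.max_span:
                    continue
                out_strand = _FLIP[p_strand] if params.invert_strand else p_strand
                if not params.strand_specific:
                    out_strand = "."
                inserted = seq[p_re:s_rs] if gap > 0 else ""
                candidates.append(
                    (coverage, best, (p_ref, out_strand, start, end, inserted))
                )
        if not candidates:
            continue
        best_score = max((c, b) for c, b, _ in candidates)
        tied = {key for c, b, key in candidates if (c, b) == best_score}
        if len(tied) == 1:
            keys.add(tied.pop())
    return keys


def brute_force_maximal_matches(read_seq: str, genome: Mapping, min_len: int) -> set[tuple]:
    """All maximal exact matches of a read by exhaustive substring testing.

    Returns (read_start, read_end, ref_id, ref_start, ref_end, strand)
    tuples in forward-genome coordinates.
    """
    out = set()
    L = len(read_seq)
    for ref_id, rec in genome.items():
        for strand, oseq in (("+", rec.sequence), ("-", _rc(rec.sequence))):
            for i in range(L):
                for jlen in range(min_len, L - i + 1):
                    part = read_seq[i : i + jlen]
                    if "N" in part:
                        continue
                    for o in _occurrences(oseq, part):
                        left_ext = i > 0 and o > 0 and read_seq[i - 1] == oseq[o - 1]
                        right_ext = (
                            i + jlen < L
                            and o + jlen < len(oseq)
                            and read_seq[i + jlen] == oseq[o + jlen]
                        )
                        if left_ext or right_ext:
                            continue
                        if strand == "+":
                            rs, re_ = o, o + jlen
                        else:
                            rs, re_ = rec.length - (o + jlen), rec.length - o
                        out.add((i, i + jlen, ref_id, rs, re_, strand))
    return out


def all_pairs_overlaps(ensembles: Sequence, features: Sequence) -> dict[str, set[tuple]]:
    """Quadratic-scan feature intersection, for checking the interval index."""
    result: dict[str, set[tuple]] = {}
    for e in ensembles:
        hits = set()
        for f in features:
            if f.ref_id != e.ref_id:
                continue
            bp = min(e.end, f.end) - max(e.start, f.start)
            if bp >= 1:
                hits.add((f.ref_id, f.start, f.end, f.strand, f.feature_type, f.name, bp))
        result[e.ensemble_id] = hits
    return result
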