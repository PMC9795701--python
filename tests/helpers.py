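"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's vectorised code paths: pileups are
recounted read by read, binomial tails are summed term by term, distances
and diversity indices are computed straight from their formulas.
"""

from __future__ import annotations

import math

import numpy as np

from straintrace.formats import AlignmentRecord


def mk_read(contig, pos, seq, strand="fwd", rid="r1", q=40):
    return AlignmentRecord(
        read_id=rid,
        contig=contig,
        pos_1based=pos,
        strand=strand,
        cigar=f"{len(seq)}M",
        sequence=seq,
        base_qualities=(q,) * len(seq),
    )


def naive_pileup(reads, max_depth=10**9):
    """Per-position (base, strand) counts by an O(reads × positions) loop.

    Reads are processed in ascending (pos, read_id) order; each position
    counts at most ``max_depth`` reads.  Returns {pos: {(base, strand): n}}
    and {pos: depth_used}.
    """
    counts: dict[int, dict[tuple[str, str], int]] = {}
    used: dict[int, int] = {}
    for rec in sorted(reads, key=lambda r: (r.pos_1based, r.read_id)):
        for i, base in enumerate(rec.sequence):
            p = rec.pos_1based + i
            if used.get(p, 0) >= max_depth:
                continue
            used[p] = used.get(p, 0) + 1
            key = (base, rec.strand)
            counts.setdefault(p, {})[key] = counts.get(p, {}).get(key, 0) + 1
    return counts, used


def brute_binom_tail(n, k, p):
    """P(X >= k), X ~ Binomial(n, p), summed term by term."""
    if k <= 0:
        return 1.0
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def brute_simpson(rel):
    return 1.0 - sum(x * x for x in rel)


def brute_bray_curtis(u, v):
    num = 2.0 * sum(min(a, b) for a, b in zip(u, v))
    den = sum(u) + sum(v)
    return 1.0 - num / den


def brute_bh(p_values):
    """Benjamini–Hochberg step-up, from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


def brute_tryptic_digest(protein, missed_cleavages, min_len, max_len):
    """Cleave after K/R not followed by P, by direct scanning."""
    cut_after = [
        i
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(protein)]
    peptides = set()
    for a in range(len(boundaries) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(boundaries))):
            start, end = boundaries[a], boundaries[b]
            pep = protein[start:end]
            if min_len <= len(pep) <= max_len:
                peptides.add((pep, start + 1, end))
    return peptides


def random_reads(rng, contig, contig_len, n_reads, read_len_range=(20, 60)):
    """Random all-match reads for pileup-oracle comparisons."""
    reads = []
    for i in range(n_reads):
        length = int(rng.integers(*read_len_range))
        length = min(length, contig_len)
        pos = int(rng.integers(1, contig_len - length + 2))
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
        strand = "fwd" if rng.random() < 0.5 else "rev"
        reads.append(mk_read(contig, pos, seq, strand=strand, rid=f"r{i:05d}"))
    return reads
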