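"""Strand-resolved pileup and substitution-variant calling.

Allele depths are counted per position, base and strand from all-match
alignments.  Variant calling applies conservative metagenomic filters: a binomial-tail
Phred site quality with a minimum of 20, a minimum used depth of 10, a depth
cap of 1000 (reads beyond the cap are dropped deterministically), and haploid
genotyping by alternative-allele fraction.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
from scipy import stats

from .formats import BASES, AlignmentRecord, ReadSet, VcfVariant, cigar_has_indels, encode_seq

QUAL_CAP = 255.0

AlignmentInput = Union[ReadSet, Sequence[ReadSet], Iterable[AlignmentRecord]]


@dataclass(frozen=True, slots=True)
class StrandAlleleDepth:
    """Per-base read counts on each strand at one position."""

    count_fwd: dict[str, int]
    count_rev: dict[str, int]
    depth_used: int

    def total(self, base: str) -> int:
        return self.count_fwd.get(base, 0) + self.count_rev.get(base, 0)


@dataclass(frozen=True, slots=True)
class CallParams:
    """Variant-calling thresholds.

    ``min_qual``/``min_depth`` are the quality and depth minima (20 and 10);
    ``max_depth`` caps the per-position depth used for counting (1000);
    ``gt_alt_fraction`` is the alternative-allele fraction at or above which
    the haploid genotype is 1; ``error_rate`` is the per-base sequencing error
    probability assumed by the site-quality model.
    """

    min_qual: float = 20.0
    min_depth: int = 10
    max_depth: int = 1000
    gt_alt_fraction: float = 0.5
    error_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_depth < self.min_depth:
            raise ValueError("max_depth must be >= min_depth")
        if not 0 < self.gt_alt_fraction <= 1:
            raise ValueError("gt_alt_fraction must be in (0, 1]")
        if not 0 < self.error_rate < 1:
            raise ValueError("error_rate must be in (0, 1)")


class Pileup(Mapping):
    """Mapping position → :class:`StrandAlleleDepth`, backed by a count array.

    ``counts`` has shape (contig_length, 4, 2): base (ACGT order) × strand
    (forward, reverse).  Only covered positions are exposed by the mapping
    interface.
    """

    def __init__(self, contig: str, counts: np.ndarray, n_skipped: int = 0) -> None:
        self.contig = contig
        self.counts = counts
        self.n_skipped = n_skipped
        self._depth = counts.sum(axis=(1, 2))
        self._covered = np.flatnonzero(self._depth > 0) + 1  # 1-based

    # -- mapping interface ---------------------------------------------------
    def __getitem__(self, pos: int) -> StrandAlleleDepth:
        if not 1 <= pos <= self.counts.shape[0] or self._depth[pos - 1] == 0:
            raise KeyError(pos)
        c = self.counts[pos - 1]
        return StrandAlleleDepth(
            count_fwd={b: int(c[i, 0]) for i, b in enumerate(BASES)},
            count_rev={b: int(c[i, 1]) for i, b in enumerate(BASES)},
            depth_used=int(self._depth[pos - 1]),
        )

    def __iter__(self) -> Iterator[int]:
        return iter(int(p) for p in self._covered)

    def __len__(self) -> int:
        return len(self._covered)

    # -- convenience ----------------------------------------------------------
    def depth(self, pos: int) -> int:
        if not 1 <= pos <= self.counts.shape[0]:
            return 0
        return int(self._depth[pos - 1])

    def allele_depths(self, pos: int, ref: str, alt: str) -> tuple[tuple[int, int], tuple[int, int]]:
        """(ADF, ADR) = ((ref_fwd, alt_fwd), (ref_rev, alt_rev)) at ``pos``."""
        if not 1 <= pos <= self.counts.shape[0]:
            return (0, 0), (0, 0)
        c = self.counts[pos - 1]
        ri, ai = BASES.index(ref), BASES.index(alt)
        return (int(c[ri, 0]), int(c[ai, 0])), (int(c[ri, 1]), int(c[ai, 1]))

    def genotype(self, pos: int, ref: str, alt: str, gt_alt_fraction: float = 0.5) -> int | None:
        """Haploid genotype at ``pos``; None when ref+alt depth is zero."""
        (rf, af), (rr, ar) = self.allele_depths(pos, ref, alt)
        n_ref, n_alt = rf + rr, af + ar
        if n_ref + n_alt == 0:
            return None
        return 1 if n_alt / (n_ref + n_alt) >= gt_alt_fraction else 0


def _iter_readsets(alignments: AlignmentInput, contig: str):
    """Normalise the accepted alignment inputs to (readsets, n_skipped)."""
    n_skipped = 0
    readsets: list[ReadSet] = []
    if isinstance(alignments, ReadSet):
        alignments = [alignments]
    alignments = list(alignments)
    if alignments and isinstance(alignments[0], ReadSet):
        readsets = [rs for rs in alignments if rs.contig == contig]
    else:
        by_len: dict[int, dict[str, list]] = {}
        for rec in alignments:
            if rec.contig != contig:
                raise ValueError(f"alignment {rec.read_id} references {rec.contig}, not {contig}")
            if cigar_has_indels(rec.cigar):
                n_skipped += 1
                continue
            grp = by_len.setdefault(len(rec.sequence), {"starts": [], "strands": [], "seqs": [], "ids": []})
            grp["starts"].append(rec.pos_1based)
            grp["strands"].append(rec.strand == "fwd")
            grp["seqs"].append(encode_seq(rec.sequence))
            grp["ids"].append(rec.read_id)
        for length, grp in by_len.items():
            readsets.append(
                ReadSet(
                    contig=contig,
                    starts=np.array(grp["starts"], dtype=np.int64),
                    strands=np.array(grp["strands"], dtype=bool),
                    seqs=np.vstack(grp["seqs"]) if grp["seqs"] else np.empty((0, length), np.uint8),
                    qual_phred=40,
                    read_ids=grp["ids"],
                )
            )
    return readsets, n_skipped


def pileup_counts(
    alignments: AlignmentInput,
    contig: str,
    contig_length: int,
    max_depth: int = 1000,
) -> Pileup:
    """Count strand-resolved allele depths over ``contig``.

    When coverage at a position exceeds ``max_depth``, reads are dropped
    deterministically: reads are ordered by (start position, read id) and each
    position counts only the first ``max_depth`` reads that cover it.
    """
    readsets, n_skipped = _iter_readsets(alignments, contig)
    counts = np.zeros((contig_length, 4, 2), dtype=np.int64)
    total = sum(len(rs) for rs in readsets)
    if total == 0:
        return Pileup(contig, counts, n_skipped)

    # quick coverage check for the uncapped fast path
    depth = np.zeros(contig_length + 1, dtype=np.int64)
    for rs in readsets:
        if len(rs) == 0:
            continue
        np.add.at(depth, rs.starts - 1, 1)
        ends = np.minimum(rs.starts - 1 + rs.read_length, contig_length)
        np.add.at(depth, ends, -1)
    exceeds = bool((np.cumsum(depth[:-1]) > max_depth).any())

    if not exceeds:
        for rs in readsets:
            n = len(rs)
            if n == 0:
                continue
            length = rs.read_length
            pos_idx = rs.starts[:, None] - 1 + np.arange(length)[None, :]
            valid = pos_idx < contig_length
            strand_idx = np.where(rs.strands, 0, 1)[:, None]
            flat = (pos_idx * 8 + rs.seqs.astype(np.int64) * 2 + strand_idx)[valid]
            counts += np.bincount(flat, minlength=contig_length * 8).reshape(
                contig_length, 4, 2
            )
        return Pileup(contig, counts, n_skipped)

    # capped path: iterate reads in (start, read_id) order with per-position caps
    reads = []
    for rs in readsets:
        ids = rs.ids
        for i in range(len(rs)):
            reads.append((int(rs.starts[i]), ids[i], rs.seqs[i], bool(rs.strands[i])))
    reads.sort(key=lambda r: (r[0], r[1]))
    used = np.zeros(contig_length, dtype=np.int64)
    for start, _rid, seq, fwd in reads:
        end = min(start - 1 + len(seq), contig_length)
        pos = np.arange(start - 1, end)
        mask = used[pos] < max_depth
        sel = pos[mask]
        counts[sel, seq[: end - start + 1][mask], 0 if fwd else 1] += 1
        used[sel] += 1
    return Pileup(contig, counts, n_skipped)


def site_quality(n_ref: int, n_alt: int, error_rate: float) -> float:
    """Phred-scaled binomial-tail site quality.

    Returns ``-10·log10 P(X >= n_alt)`` with ``X ~ Binomial(n_ref + n_alt,
    error_rate)``, capped at 255.  Zero observations (or no alternative
    reads) yield 0.
    """
    if n_ref < 0 or n_alt < 0:
        raise ValueError("allele counts must be non-negative")
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    n = n_ref + n_alt
    if n == 0 or n_alt == 0:
        return 0.0
    logp = stats.binom.logsf(n_alt - 1, n, error_rate)
    qual = -10.0 * logp / math.log(10.0)
    return float(min(qual, QUAL_CAP))


def _site_quality_vec(n_ref: np.ndarray, n_alt: np.ndarray, error_rate: float) -> np.ndarray:
    n = n_ref + n_alt
    with np.errstate(divide="ignore"):
        logp = stats.binom.logsf(n_alt - 1, np.maximum(n, 1), error_rate)
    qual = -10.0 * logp / math.log(10.0)
    qual = np.where((n == 0) | (n_alt == 0), 0.0, qual)
    return np.minimum(qual, QUAL_CAP)


def call_variants(
    pileup: Pileup, contig_seq: str, params: CallParams | None = None
) -> list[VcfVariant]:
    """Call filtered substitutions from a pileup.

    At each covered position the alternative allele is the non-reference base
    with the highest total count (ties broken alphabetically).  A variant is
    emitted iff the alternative count is positive, the binomial-tail quality
    is at least ``min_qual`` and the used depth is at least ``min_depth``.
    The haploid genotype is 1 iff alt/(ref+alt) ≥ ``gt_alt_fraction``.
    """
    params = params or CallParams()
    L = pileup.counts.shape[0]
    if len(contig_seq) < L:
        raise ValueError("contig sequence shorter than pileup extent")
    totals = pileup.counts.sum(axis=2)  # (L, 4)
    depth_used = totals.sum(axis=1)
    ref_codes = encode_seq(contig_seq[:L]).astype(np.int64)
    masked = totals.copy()
    masked[np.arange(L), ref_codes] = -1
    alt_codes = masked.argmax(axis=1)  # alphabetical tie-break: argmax takes first
    alt_total = masked[np.arange(L), alt_codes]
    ref_total = totals[np.arange(L), ref_codes]

    candidate = (alt_total > 0) & (depth_used >= params.min_depth)
    idx = np.flatnonzero(candidate)
    if idx.size == 0:
        return []
    quals = _site_quality_vec(ref_total[idx], alt_total[idx], params.error_rate)
    quals = np.round(quals, 3)
    keep = quals >= params.min_qual
    out: list[VcfVariant] = []
    for pos0, q in zip(idx[keep], quals[keep]):
        ref_b = BASES[ref_codes[pos0]]
        alt_b = BASES[alt_codes[pos0]]
        c = pileup.counts[pos0]
        n_ref, n_alt = int(ref_total[pos0]), int(alt_total[pos0])
        gt = 1 if n_alt / (n_ref + n_alt) >= params.gt_alt_fraction else 0
        out.append(
            VcfVariant(
                contig=pileup.contig,
                pos_1based=int(pos0) + 1,
                ref=ref_b,
                alt=alt_b,
                qual=float(q),
                depth=int(depth_used[pos0]),
                genotype=gt,
                adf=(int(c[ref_codes[pos0], 0]), int(c[alt_codes[pos0], 0])),
                adr=(int(c[ref_codes[pos0], 1]), int(c[alt_codes[pos0], 1])),
            )
        )
    return out
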