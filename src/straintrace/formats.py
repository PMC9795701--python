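"""Readers and writers for the text formats the pipeline touches.

The pipeline works with a deliberately small subset of each format:

* SAM: single-end, all-match alignments (CIGAR ``<n>M``), flags 0/4/16,
  constant-quality bases.  Records are parsed line by line so that malformed
  records can be skipped with a warning instead of aborting the whole file.
* VCF 4.2: haploid single-sample substitution records with ``DP`` in INFO and
  ``GT``/``ADF``/``ADR`` FORMAT fields.  Indel lines are skipped on read,
  multi-allelic lines are rejected.
* GFF3: ``CDS`` features with 1-based inclusive coordinates, strand and frame.
* Plain TSV for taxonomy, sample metadata and peptide observations.

All coordinates are 1-based inclusive at every file boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

CONDITIONS = ("T1DM", "control")
SITES = ("oral", "gut")
OMES = ("MG", "MT", "MP")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# core record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """One biological sample: an (individual, visit, site, ome) combination."""

    sample_id: str
    individual: str
    family: str
    visit: int
    condition: str  # "T1DM" | "control"
    site: str  # "oral" | "gut"
    ome: str  # "MG" | "MT" | "MP"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}: {self.condition}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}: {self.site}")
        if self.ome not in OMES:
            raise ValueError(f"ome must be one of {OMES}: {self.ome}")
        if not self.family:
            raise ValueError("family must be non-empty")


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """A single-end alignment of one read to a contig (1-based, all-match)."""

    read_id: str
    contig: str
    pos_1based: int
    strand: str  # "fwd" | "rev"
    cigar: str
    sequence: str
    base_qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pos_1based < 1:
            raise ValueError("pos_1based must be >= 1")
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError("sequence and base_qualities lengths differ")
        if cigar_query_length(self.cigar) != len(self.sequence):
            raise ValueError("CIGAR does not consume the query length")

    @property
    def end_1based(self) -> int:
        """Last reference position covered (all-match reads)."""
        return self.pos_1based + len(self.sequence) - 1


@dataclass(frozen=True, slots=True)
class VcfVariant:
    """A substitution call on a contig with strand-resolved allelic depths.

    ``adf``/``adr`` hold (ref, alt) read counts on the forward/reverse strand;
    ``genotype`` is haploid (0 reference-like, 1 alternative).  QUAL is stored
    at 3-decimal precision so the VCF round trip is an identity.
    """

    contig: str
    pos_1based: int
    ref: str
    alt: str
    qual: float
    depth: int
    genotype: int
    adf: tuple[int, int]
    adr: tuple[int, int]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.genotype not in (0, 1):
            raise ValueError("genotype must be 0 or 1")
        object.__setattr__(self, "qual", round(float(self.qual), 3))
        object.__setattr__(self, "adf", tuple(int(x) for x in self.adf))
        object.__setattr__(self, "adr", tuple(int(x) for x in self.adr))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos_1based, self.ref, self.alt)


@dataclass(frozen=True, slots=True)
class GeneModel:
    """An ORF on a contig: 1-based inclusive coordinates, strand and frame."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str  # "+" | "-"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad coordinates for {self.gene_id}")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# packed alignments
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Fixed-length, all-match alignments against one contig, held as arrays.

    This is the vectorised twin of a list of :class:`AlignmentRecord`: the
    simulator emits it directly and the pileup/extraction code consumes it
    without per-read Python objects.
    """

    contig: str
    starts: np.ndarray  # (n,) int64, 1-based
    strands: np.ndarray  # (n,) bool, True = forward
    seqs: np.ndarray  # (n, read_length) uint8 base codes
    qual_phred: int
    sample_id: str = ""
    read_ids: list[str] | None = None

    def __len__(self) -> int:
        return int(self.starts.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.seqs.shape[1]) if len(self) else 0

    @property
    def ids(self) -> list[str]:
        if self.read_ids is None:
            prefix = f"{self.sample_id}:{self.contig}" if self.sample_id else self.contig
            self.read_ids = [f"{prefix}:{i}" for i in range(len(self))]
        return self.read_ids

    def to_records(self) -> list[AlignmentRecord]:
        n, length = len(self), self.read_length
        quals = (self.qual_phred,) * length
        cigar = f"{length}M"
        ids = self.ids
        return [
            AlignmentRecord(
                read_id=ids[i],
                contig=self.contig,
                pos_1based=int(self.starts[i]),
                strand="fwd" if self.strands[i] else "rev",
                cigar=cigar,
                sequence=decode_seq(self.seqs[i]),
                base_qualities=quals,
            )
            for i in range(n)
        ]


def records_to_readsets(records: Iterable[AlignmentRecord]) -> list[ReadSet]:
    """Group all-match records into per-(contig, length, quality) ReadSets."""
    groups: dict[tuple[str, int, int], list[AlignmentRecord]] = {}
    for rec in records:
        qual = rec.base_qualities[0] if rec.base_qualities else 40
        groups.setdefault((rec.contig, len(rec.sequence), int(qual)), []).append(rec)
    out = []
    for (contig, length, qual), recs in groups.items():
        out.append(
            ReadSet(
                contig=contig,
                starts=np.array([r.pos_1based for r in recs], dtype=np.int64),
                strands=np.array([r.strand == "fwd" for r in recs], dtype=bool),
                seqs=np.vstack([encode_seq(r.sequence) for r in recs])
                if recs
                else np.empty((0, length), dtype=np.uint8),
                qual_phred=qual,
                read_ids=[r.read_id for r in recs],
            )
        )
    return out


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def cigar_query_length(cigar: str) -> int:
    """Number of query bases a CIGAR string consumes."""
    if cigar == "*":
        return 0
    total = 0
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in "MIS=X":
            total += n
        consumed += m.end() - m.start()
    if consumed != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return total


def cigar_has_indels(cigar: str) -> bool:
    return any(op in "IDN" for _, op in _CIGAR_RE.findall(cigar))


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Read the supported SAM subset; skip malformed or unmapped records.

    Requires at least one ``@SQ`` header line.  Malformed records (too few
    fields, CIGAR/sequence length mismatch, missing sequence) are skipped with
    a warning naming the line number.
    """
    path = Path(path)
    records: list[AlignmentRecord] = []
    saw_sq = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    saw_sq = True
                continue
            if not saw_sq:
                raise ValueError(f"{path}: missing @SQ header lines before alignments")
            fields = line.split("\t")
            if len(fields) < 11:
                logger.warning("%s line %d: fewer than 11 SAM fields, skipped", path, lineno)
                continue
            qname, flag_s, rname, pos_s, _mapq, cigar, _rnext, _pnext, _tlen, seq, qual = fields[:11]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError:
                logger.warning("%s line %d: non-integer FLAG/POS, skipped", path, lineno)
                continue
            if flag & 4:  # unmapped
                continue
            if seq == "*":
                logger.warning("%s line %d: missing sequence, skipped", path, lineno)
                continue
            try:
                if cigar_query_length(cigar) != len(seq):
                    logger.warning(
                        "%s line %d: CIGAR %s does not consume %d query bases, skipped",
                        path, lineno, cigar, len(seq),
                    )
                    continue
            except ValueError:
                logger.warning("%s line %d: malformed CIGAR %r, skipped", path, lineno, cigar)
                continue
            quals = (
                tuple(ord(c) - 33 for c in qual) if qual != "*" else (40,) * len(seq)
            )
            if len(quals) != len(seq):
                logger.warning("%s line %d: QUAL length mismatch, skipped", path, lineno)
                continue
            records.append(
                AlignmentRecord(
                    read_id=qname,
                    contig=rname,
                    pos_1based=pos,
                    strand="rev" if flag & 16 else "fwd",
                    cigar=cigar,
                    sequence=seq.upper(),
                    base_qualities=quals,
                )
            )
    return records


def write_sam(
    alignments: Sequence[ReadSet] | Sequence[AlignmentRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write alignments as SAM (flags 0/16, MAPQ 60)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for item in alignments:
            if isinstance(item, ReadSet):
                ids = item.ids
                qual_char = chr(item.qual_phred + 33)
                length = item.read_length
                qual_str = qual_char * length
                cigar = f"{length}M"
                for i in range(len(item)):
                    flag = 0 if item.strands[i] else 16
                    fh.write(
                        f"{ids[i]}\t{flag}\t{item.contig}\t{int(item.starts[i])}\t60\t"
                        f"{cigar}\t*\t0\t0\t{decode_seq(item.seqs[i])}\t{qual_str}\n"
                    )
            else:
                rec = item
                flag = 0 if rec.strand == "fwd" else 16
                qual_str = "".join(chr(q + 33) for q in rec.base_qualities)
                fh.write(
                    f"{rec.read_id}\t{flag}\t{rec.contig}\t{rec.pos_1based}\t60\t"
                    f"{rec.cigar}\t*\t0\t0\t{rec.sequence}\t{qual_str}\n"
                )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=straintrace
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth used for calling">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype (0 ref, 1 alt)">
##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Allelic depths on the forward strand (ref, alt)">
##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Allelic depths on the reverse strand (ref, alt)">
"""


def write_variants(variants: Sequence[VcfVariant], path: str | Path) -> None:
    """Write substitution calls as single-sample VCF 4.2.

    Input must be sorted by (contig, pos).
    """
    keys = [(v.contig, v.pos_1based) for v in variants]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (contig, pos)")
    contigs = dict.fromkeys(v.contig for v in variants)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for v in variants:
            fh.write(
                f"{v.contig}\t{v.pos_1based}\t.\t{v.ref}\t{v.alt}\t{v.qual:.3f}\tPASS\t"
                f"DP={v.depth}\tGT:ADF:ADR\t{v.genotype}:{v.adf[0]},{v.adf[1]}:"
                f"{v.adr[0]},{v.adr[1]}\n"
            )


def read_variants(path: str | Path) -> list[VcfVariant]:
    """Read single-sample substitution records from a VCF.

    Indel lines (REF or ALT longer than one base) are skipped with a warning;
    multi-allelic lines are rejected with an error.
    """
    out: list[VcfVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) > 1:
                raise ValueError(
                    f"{path}: multi-allelic record at {rec.contig}:{rec.pos} is not supported"
                )
            if not alts:
                continue
            alt = alts[0]
            if len(rec.ref) != 1 or len(alt) != 1:
                logger.warning(
                    "%s: indel record at %s:%d skipped", path, rec.contig, rec.pos
                )
                continue
            if not sample_names:
                raise ValueError(f"{path}: VCF has no sample column")
            smp = rec.samples[sample_names[0]]
            gt = smp["GT"]
            gt_val = int(gt[0]) if isinstance(gt, tuple) else int(gt)
            adf = tuple(int(x) for x in smp["ADF"])
            adr = tuple(int(x) for x in smp["ADR"])
            out.append(
                VcfVariant(
                    contig=rec.contig,
                    pos_1based=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    depth=int(rec.info["DP"]),
                    genotype=gt_val,
                    adf=adf,
                    adr=adr,
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA / GFF3 / TSV annotation bundle
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tstraintrace\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t"
                f"{g.frame}\tID={g.gene_id}\n"
            )


def read_gff(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path} line {lineno}: expected 9 GFF columns")
            contig, _src, ftype, start, end, _score, strand, frame, attrs = fields
            if ftype != "CDS":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            if gene_id is None:
                raise ValueError(f"{path} line {lineno}: CDS feature without ID attribute")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    frame=0 if frame == "." else int(frame),
                )
            )
    return genes


def write_taxonomy(contig_to_genus: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"contig_id": list(contig_to_genus), "genus": list(contig_to_genus.values())}
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["contig_id"], df["genus"]))


def read_annotations(
    fasta_path: str | Path, gff_path: str | Path, taxonomy_path: str | Path
) -> tuple[dict[str, str], list[GeneModel], dict[str, str]]:
    """Load contigs, gene models and the contig→genus table together.

    Every gene must lie within its contig; contigs absent from the taxonomy
    table are assigned genus ``"unclassified"``.
    """
    contigs = read_fasta(fasta_path)
    genes = read_gff(gff_path)
    for g in genes:
        if g.contig not in contigs:
            raise ValueError(f"gene {g.gene_id} references unknown contig {g.contig}")
        if g.end > len(contigs[g.contig]):
            raise ValueError(
                f"gene {g.gene_id} exceeds contig {g.contig} bounds "
                f"({g.end} > {len(contigs[g.contig])})"
            )
    taxonomy = read_taxonomy(taxonomy_path)
    genus_map = {c: taxonomy.get(c, "unclassified") for c in contigs}
    return contigs, genes, genus_map


# ---------------------------------------------------------------------------
# metadata / peptides
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "individual", "family", "visit", "condition", "site", "ome"]


def write_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [{c: getattr(s, c) for c in METADATA_COLUMNS} for s in samples]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"visit": int})
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            individual=row.individual,
            family=str(row.family),
            visit=int(row.visit),
            condition=row.condition,
            site=row.site,
            ome=row.ome,
        )
        for row in df.itertuples()
    ]
    seen: set[tuple] = set()
    for s in samples:
        key = (s.individual, s.visit, s.site, s.ome)
        if key in seen:
            raise ValueError(f"duplicate sample for {key}")
        seen.add(key)
    return samples


PEPTIDE_COLUMNS = ["sample_id", "peptide", "spectral_count"]


def write_peptides(table: pd.DataFrame, path: str | Path) -> None:
    table[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_peptides(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: peptide table missing columns {sorted(missing)}")
    return df
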