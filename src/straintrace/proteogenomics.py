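"""Variant-effect annotation, protein search-database assembly and
variant-peptide matching.

A substitution inside an ORF is classified by locating its codon (respecting
strand and frame), translating both alleles with the standard genetic code
and comparing residues: synonymous (identical), nonsense (alternative codon
is a stop) or missense.  Each missense variant yields one variant protein
carrying a single substituted residue; tryptic peptides of that protein that
span the substituted residue and do not occur in the reference proteome
digest are the variant-specific peptides that can confer metaproteomic
support.

Search databases are assembled per sample with an individual→family fallback,
size-filtered to 60–40,000 residues, deduplicated by sequence, and doubled
with reversed-sequence decoys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from pyteomics import parser as pyt_parser

from .formats import GeneModel, SampleMeta, VcfVariant

logger = logging.getLogger(__name__)

TRYPSIN_RULE = r"[KR](?!P)"  # cleave C-terminal of K/R except before proline

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def gene_coding_sequence(gene: GeneModel, contig_seq: str) -> str:
    """Coding-strand nucleotide sequence of the gene, frame applied."""
    segment = contig_seq[gene.start - 1 : gene.end]
    if gene.strand == "-":
        segment = _revcomp(segment)
    return segment[gene.frame :]


def protein_sequence(gene: GeneModel, contig_seq: str) -> str:
    """Translated protein, trailing stop removed."""
    cds = gene_coding_sequence(gene, contig_seq)
    cds = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(cds).translate())
    return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True, slots=True)
class VariantProtein:
    """A protein sequence carrying exactly one substituted residue."""

    protein_id: str
    sequence: str
    variant_residue_index: int  # 1-based
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt residues must differ")
        if self.sequence[self.variant_residue_index - 1] != self.alt_aa:
            raise ValueError("sequence does not carry the alternative residue")


@dataclass
class SearchDatabase:
    """Protein search database: targets plus reversed-sequence decoys."""

    entries: dict[str, str]
    provenance: str = ""
    decoys_included: bool = True

    @property
    def targets(self) -> dict[str, str]:
        return {k: v for k, v in self.entries.items() if not k.startswith("DECOY_")}


@dataclass(slots=True)
class VariantPeptideHit:
    """An observed peptide that uniquely supports one variant protein."""

    peptide: str
    protein_id: str
    sample: str
    spectral_count: int
    variant: object | None = None  # the TrackedVariant this protein derives from

    def __post_init__(self) -> None:
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be >= 1")


# ---------------------------------------------------------------------------
# effect annotation
# ---------------------------------------------------------------------------


def annotate_variant_effect(
    variant: VcfVariant, gene: GeneModel | None, contig_seq: str
) -> tuple[str, VariantProtein | None]:
    """Classify a substitution against a gene model.

    Returns (effect, variant_protein) where effect is one of "synonymous",
    "missense", "nonsense" or "intergenic"; a missense effect comes with the
    variant protein.  Positions outside any gene, ahead of the frame offset or
    in an incomplete terminal codon are classified "intergenic".
    """
    pos = variant.pos_1based
    if gene is None or not gene.contains(pos):
        return "intergenic", None
    if contig_seq[pos - 1] != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.contig}:{pos}: "
            f"contig has {contig_seq[pos - 1]}, variant says {variant.ref}"
        )
    # index of the variant base along the coding strand
    if gene.strand == "+":
        coding_off = pos - gene.start - gene.frame
        coding_base = variant.alt
    else:
        coding_off = gene.end - pos - gene.frame
        coding_base = variant.alt.translate(_COMPLEMENT)
    if coding_off < 0:
        logger.warning(
            "variant %s:%d precedes the frame offset of %s; treated as intergenic",
            variant.contig, pos, gene.gene_id,
        )
        return "intergenic", None
    cds = gene_coding_sequence(gene, contig_seq)
    codon_i = coding_off // 3
    codon_start = 3 * codon_i
    if codon_start + 3 > len(cds):
        logger.warning(
            "variant %s:%d falls in an incomplete terminal codon of %s; "
            "treated as intergenic",
            variant.contig, pos, gene.gene_id,
        )
        return "intergenic", None
    ref_codon = cds[codon_start : codon_start + 3]
    within = coding_off % 3
    alt_codon = ref_codon[:within] + coding_base + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous", None
    if alt_aa == "*":
        return "nonsense", None
    protein = protein_sequence(gene, contig_seq)
    residue_index = codon_i + 1
    if residue_index > len(protein):  # substitution in the terminal stop codon
        mutated = protein + alt_aa
    else:
        mutated = protein[: residue_index - 1] + alt_aa + protein[residue_index:]
    vp = VariantProtein(
        protein_id=f"{gene.gene_id}|p.{ref_aa}{residue_index}{alt_aa}",
        sequence=mutated,
        variant_residue_index=residue_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )
    return "missense", vp


def find_gene(genes: Sequence[GeneModel], contig: str, pos: int) -> GeneModel | None:
    """First gene on ``contig`` containing ``pos`` (genes do not overlap)."""
    for g in genes:
        if g.contig == contig and g.contains(pos):
            return g
    return None


# ---------------------------------------------------------------------------
# database assembly
# ---------------------------------------------------------------------------


def select_database(
    sample_id: str,
    available: Mapping[str, Mapping[str, str]],
    metadata: Sequence[SampleMeta],
) -> tuple[str, dict[str, str]]:
    """Resolve the protein pool for a sample with individual/family fallback.

    Chain: the sample's own database → concatenation of all databases of the
    sample's individual → concatenation of all databases of the individual's
    family.  Returns (provenance level, pool).
    """
    by_id = {s.sample_id: s for s in metadata}
    if sample_id not in by_id:
        raise KeyError(f"sample {sample_id} not in metadata")
    meta = by_id[sample_id]
    if available.get(sample_id):
        return "sample", dict(available[sample_id])
    pool: dict[str, str] = {}
    for s in metadata:
        if s.individual == meta.individual and available.get(s.sample_id):
            pool.update(available[s.sample_id])
    if pool:
        return "individual", pool
    for s in metadata:
        if s.family == meta.family and available.get(s.sample_id):
            pool.update(available[s.sample_id])
    if pool:
        return "family", pool
    raise ValueError(f"no protein database available at any level for family {meta.family}")


def build_search_database(
    microbial: Mapping[str, str],
    variant_proteins: Iterable[VariantProtein] = (),
    host: Mapping[str, str] | None = None,
    contaminants: Mapping[str, str] | None = None,
    min_len: int = 60,
    max_len: int = 40_000,
    provenance: str = "",
) -> SearchDatabase:
    """Assemble a size-filtered, deduplicated target-decoy database.

    Sequences shorter than ``min_len`` or longer than ``max_len`` residues are
    removed; exact duplicate sequences are collapsed keeping the
    lexicographically smallest identifier; reversed-sequence decoys with a
    ``DECOY_`` prefix are appended.
    """
    pool: dict[str, str] = {}
    pool.update(microbial)
    for vp in variant_proteins:
        pool[vp.protein_id] = vp.sequence
    pool.update(host or {})
    pool.update(contaminants or {})

    by_seq: dict[str, str] = {}
    for pid in sorted(pool):
        seq = pool[pid].upper()
        if not min_len <= len(seq) <= max_len:
            continue
        if seq not in by_seq or pid < by_seq[seq]:
            by_seq[seq] = pid
    if not by_seq:
        raise ValueError("database is empty after the size filter")
    targets = {pid: seq for seq, pid in sorted(by_seq.items(), key=lambda kv: kv[1])}
    entries = dict(targets)
    for pid, seq in targets.items():
        entries[f"DECOY_{pid}"] = seq[::-1]
    return SearchDatabase(entries=entries, provenance=provenance, decoys_included=True)


# ---------------------------------------------------------------------------
# digestion and matching
# ---------------------------------------------------------------------------


def tryptic_digest(
    protein: str,
    missed_cleavages: int = 2,
    min_pep_len: int = 7,
    max_pep_len: int = 50,
) -> list[tuple[str, int, int]]:
    """In-silico tryptic peptides with 1-based inclusive residue spans.

    Cleaves C-terminal of K/R unless followed by P; retains peptides with up
    to ``missed_cleavages`` internal sites and length within
    [``min_pep_len``, ``max_pep_len``].
    """
    if not protein:
        raise ValueError("protein sequence must be non-empty")
    seen: set[tuple[int, str]] = set()
    out: list[tuple[str, int, int]] = []
    for start0, pep in pyt_parser.icleave(protein, TRYPSIN_RULE, missed_cleavages):
        if (start0, pep) in seen:
            continue
        seen.add((start0, pep))
        if min_pep_len <= len(pep) <= max_pep_len:
            out.append((pep, start0 + 1, start0 + len(pep)))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def reference_peptide_set(
    reference_proteome: Mapping[str, str],
    missed_cleavages: int = 2,
    min_pep_len: int = 7,
    max_pep_len: int = 50,
) -> set[str]:
    """All tryptic peptides of the reference (non-variant) proteome."""
    peptides: set[str] = set()
    for seq in reference_proteome.values():
        if seq:
            peptides.update(p for p, _s, _e in tryptic_digest(seq, missed_cleavages, min_pep_len, max_pep_len))
    return peptides


def variant_spanning_peptides(
    vp: VariantProtein,
    missed_cleavages: int = 2,
    min_pep_len: int = 7,
    max_pep_len: int = 50,
) -> list[str]:
    """Tryptic peptides of a variant protein that span the substituted residue."""
    idx = vp.variant_residue_index
    return [
        pep
        for pep, start, end in tryptic_digest(vp.sequence, missed_cleavages, min_pep_len, max_pep_len)
        if start <= idx <= end
    ]


def match_variant_peptides(
    observed: pd.DataFrame,
    db: SearchDatabase | None,
    variant_proteins: Sequence[VariantProtein],
    reference_proteome: Mapping[str, str],
    missed_cleavages: int = 2,
    min_pep_len: int = 7,
    max_pep_len: int = 50,
) -> list[VariantPeptideHit]:
    """Confer metaproteomic support on variants via exact peptide matches.

    A hit requires an observed peptide to equal a tryptic peptide of a
    variant protein that spans the substituted residue AND to be absent from
    the tryptic digest of the reference proteome.  When a database is given,
    only variant proteins whose sequence survived database construction are
    considered.  Spectral counts are summed per (sample, peptide, protein).
    """
    ref_peps = reference_peptide_set(reference_proteome, missed_cleavages, min_pep_len, max_pep_len)
    db_seqs = set(db.targets.values()) if db is not None else None
    candidates: dict[str, list[VariantProtein]] = {}
    for vp in variant_proteins:
        if db_seqs is not None and vp.sequence not in db_seqs:
            continue
        for pep in variant_spanning_peptides(vp, missed_cleavages, min_pep_len, max_pep_len):
            if pep in ref_peps:
                continue
            candidates.setdefault(pep, []).append(vp)

    hits: dict[tuple[str, str, str], int] = {}
    for row in observed.itertuples():
        pep = row.peptide
        if pep not in candidates:
            continue
        for vp in candidates[pep]:
            key = (row.sample_id, pep, vp.protein_id)
            hits[key] = hits.get(key, 0) + int(row.spectral_count)
    return [
        VariantPeptideHit(peptide=pep, protein_id=pid, sample=sample, spectral_count=count)
        for (sample, pep, pid), count in sorted(hits.items())
    ]
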