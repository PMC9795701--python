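"""Synthetic multi-omic cohort generator with planted strain variants.

Emulates a family-structured cohort sampled at both ends of the
gastrointestinal tract: families with type 1 diabetes (T1DM) cases and
healthy members, repeated visits, and per-sample metagenomic (DNA),
metatranscriptomic (RNA) and metaproteomic (peptide) observations over a set
of genus-assigned contigs.  Substitution variants are planted on the contigs;
every individual carries them in the oral community and transmits each to the
gut with a per-(genus, condition) probability.  DNA/RNA reads are
strand-balanced, all-match, fixed-length, with a uniform base-error channel;
peptide observations are tryptic fragments of expressed proteins, including
variant-spanning peptides for transmitted missense variants.

Everything is deterministic for a fixed seed: independent generator streams
are derived from (seed, stream, sample) so outputs are byte-identical across
runs and independent of evaluation order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .formats import (
    BASES,
    GeneModel,
    ReadSet,
    SampleMeta,
    VcfVariant,
    decode_seq,
    encode_seq,
    write_fasta,
    write_gff,
    write_metadata,
    write_peptides,
    write_sam,
    write_taxonomy,
)
from .proteogenomics import (
    annotate_variant_effect,
    protein_sequence,
    reference_peptide_set,
    tryptic_digest,
)

# minimum planted-variant spacing within a gene, in bp.  Guarantees that no
# tryptic peptide (<= 50 residues) can span two planted variants, so every
# emitted variant peptide carries exactly one substitution.
MIN_VARIANT_SPACING_BP = 153

_SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class TaxonSpec(NamedTuple):
    """One genus in the synthetic community."""

    genus: str
    n_contigs: int
    contig_length_bp: int
    oral_abundance_weight: float
    gut_abundance_weight: float


DEFAULT_TAXA = (
    # genera highlighted by the transfer analysis; weights reflect the
    # oral-high / gut-high prevalence contrast between the two body sites
    TaxonSpec("Prevotella", 2, 2000, 1.5, 0.8),
    TaxonSpec("Streptococcus", 2, 2000, 1.5, 0.6),
    TaxonSpec("Bacteroides", 2, 2000, 0.4, 1.6),
    TaxonSpec("Alistipes", 2, 2000, 0.6, 1.2),
    TaxonSpec("Bifidobacterium", 2, 2000, 0.8, 1.0),
    TaxonSpec("Faecalibacterium", 2, 2000, 0.4, 1.4),
)

# the cohort's central transmission contrast: Streptococcus is transmitted
# less often in T1DM than in controls; other genera do not differ
DEFAULT_TRANSMISSION = {("Streptococcus", "T1DM"): 0.2, ("Streptococcus", "control"): 0.6}
DEFAULT_TRANSMISSION_BASELINE = 0.5


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Coverages are mean fold-coverages (DNA: per strand); ``transmission_prob``
    maps (genus, condition) to the probability that an individual transmits a
    given oral variant to the gut (a plain float applies to everything;
    missing keys fall back to ``transmission_default``).
    """

    n_families: int = 8
    individuals_per_family: int = 4
    t1dm_fraction: float = 0.5
    visits_per_individual: int = 3
    taxa: tuple[TaxonSpec, ...] = DEFAULT_TAXA
    variants_per_taxon: int = 10
    transmission_prob: Mapping[tuple[str, str], float] | float = field(
        default_factory=lambda: dict(DEFAULT_TRANSMISSION)
    )
    transmission_default: float = DEFAULT_TRANSMISSION_BASELINE
    coverage_dna: float = 30.0
    coverage_rna: float = 20.0
    base_error_rate: float = 1e-3
    peptide_depth: float = 300.0
    read_length_bp: int = 100
    genes_per_contig: int = 2
    expressed_gene_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        self.taxa = tuple(TaxonSpec(*t) for t in self.taxa)
        self.validate()

    def validate(self) -> None:
        probs = [self.t1dm_fraction, self.base_error_rate, self.expressed_gene_fraction,
                 self.transmission_default]
        if isinstance(self.transmission_prob, Mapping):
            probs.extend(self.transmission_prob.values())
        else:
            probs.append(float(self.transmission_prob))
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if min(self.n_families, self.individuals_per_family, self.visits_per_individual,
               self.read_length_bp, self.genes_per_contig) < 1:
            raise ValueError("counts and lengths must be positive")
        if self.coverage_dna < 0 or self.coverage_rna < 0 or self.peptide_depth < 0:
            raise ValueError("coverages and peptide depth must be non-negative")
        genera = [t.genus for t in self.taxa]
        if len(set(genera)) != len(genera):
            raise ValueError("genus names must be unique")
        for t in self.taxa:
            if t.n_contigs < 1 or t.contig_length_bp < 1:
                raise ValueError(f"taxon {t.genus}: contig counts/lengths must be positive")
            if t.oral_abundance_weight < 0 or t.gut_abundance_weight < 0:
                raise ValueError(f"taxon {t.genus}: abundance weights must be non-negative")

    def transmission(self, genus: str, condition: str) -> float:
        if isinstance(self.transmission_prob, Mapping):
            return float(self.transmission_prob.get((genus, condition), self.transmission_default))
        return float(self.transmission_prob)


@dataclass(frozen=True, slots=True)
class PlantedVariant:
    """A planted substitution with its truth annotation."""

    variant_id: str
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    genus: str
    gene_id: str
    effect: str  # synonymous | missense | nonsense
    present_in_oral: bool
    present_in_gut: bool  # true iff at least one individual transmits it

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True, slots=True)
class EmittedPeptide:
    """One peptide observation in a gut metaproteomic sample."""

    sample_id: str
    peptide: str
    is_variant_spanning: bool
    variant_ids: tuple[str, ...]
    count: int


@dataclass
class CohortTruth:
    """Ground-truth ledger of a generated cohort."""

    config: CohortConfig
    sample_table: list[SampleMeta]
    contigs: dict[str, str]
    genes: list[GeneModel]
    contig_taxon: dict[str, str]
    planted_variants: list[PlantedVariant]
    transmission: dict[tuple[str, str], bool]  # (variant_id, individual) -> bool
    expression_level: dict[str, float]  # gene_id -> non-negative rate
    emitted_peptides: list[EmittedPeptide]
    variant_proteins: dict[str, object] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return sorted({s.individual for s in self.sample_table})

    def condition_of(self, individual: str) -> str:
        for s in self.sample_table:
            if s.individual == individual:
                return s.condition
        raise KeyError(individual)

    def variants_on(self, contig: str) -> list[PlantedVariant]:
        return [v for v in self.planted_variants if v.contig == contig]

    def is_present(self, variant: PlantedVariant, site: str, individual: str) -> bool:
        """Whether the variant allele is carried at a body site of an individual."""
        if site == "oral":
            return variant.present_in_oral
        return self.transmission[(variant.variant_id, individual)]

    def transmitted_variants(self, individual: str) -> list[PlantedVariant]:
        return [
            v for v in self.planted_variants if self.transmission[(v.variant_id, individual)]
        ]

    def sample(self, individual: str, visit: int, site: str, ome: str) -> SampleMeta:
        for s in self.sample_table:
            if (s.individual, s.visit, s.site, s.ome) == (individual, visit, site, ome):
                return s
        raise KeyError((individual, visit, site, ome))


def _stream(seed: int, stream: int, label: str = "") -> np.random.Generator:
    entropy = [seed, stream]
    if label:
        entropy.append(zlib.crc32(label.encode()) & 0x7FFFFFFF)
    return np.random.default_rng(entropy)


def _phred(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return int(min(40, round(-10.0 * math.log10(error_rate))))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _assign_conditions(config: CohortConfig) -> list[SampleMeta]:
    """Family/individual/visit/sample structure with round-robin conditions.

    Within each family T1DM status is assigned to alternating member slots so
    every family contains both conditions (multiplex-family design).
    """
    samples: list[SampleMeta] = []
    m = config.individuals_per_family
    n_t1dm = int(round(config.t1dm_fraction * m))
    order = list(range(0, m, 2)) + list(range(1, m, 2))
    t1dm_slots = set(order[:n_t1dm])
    for f in range(1, config.n_families + 1):
        family = f"F{f:02d}"
        for i in range(m):
            individual = f"{family}.{i + 1}"
            condition = "T1DM" if i in t1dm_slots else "control"
            for v in range(1, config.visits_per_individual + 1):
                for site, ome in (("oral", "MG"), ("gut", "MG"), ("gut", "MT"), ("gut", "MP")):
                    samples.append(
                        SampleMeta(
                            sample_id=f"{individual}_V{v}_{site}_{ome}",
                            individual=individual,
                            family=family,
                            visit=v,
                            condition=condition,
                            site=site,
                            ome=ome,
                        )
                    )
    return samples


def _build_genome(config: CohortConfig, rng: np.random.Generator):
    """Random contigs with in-frame, non-overlapping ORFs, genus-labelled."""
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    contig_taxon: dict[str, str] = {}
    margin = config.read_length_bp
    gap = 30
    for taxon in config.taxa:
        L = taxon.contig_length_bp
        usable = L - 2 * margin - (config.genes_per_contig - 1) * gap
        gene_len = 3 * (usable // config.genes_per_contig // 3)
        if gene_len < 2 * config.read_length_bp + 9:
            raise ValueError(
                f"taxon {taxon.genus}: contigs of {L} bp are too short to host "
                f"{config.genes_per_contig} ORFs of useful size"
            )
        for j in range(taxon.n_contigs):
            name = f"{taxon.genus}_c{j + 1}"
            seq = rng.integers(0, 4, size=L, dtype=np.uint8)
            pos = margin + 1
            for k in range(config.genes_per_contig):
                n_codons = gene_len // 3
                body = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
                mrna = "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"
                strand = "+" if k % 2 == 0 else "-"
                placed = mrna if strand == "+" else _revcomp(mrna)
                seq[pos - 1 : pos - 1 + gene_len] = encode_seq(placed)
                genes.append(
                    GeneModel(
                        gene_id=f"{name}_g{k + 1}",
                        contig=name,
                        start=pos,
                        end=pos + gene_len - 1,
                        strand=strand,
                        frame=0,
                    )
                )
                pos += gene_len + gap
            contigs[name] = decode_seq(seq)
            contig_taxon[name] = taxon.genus
    return contigs, genes, contig_taxon


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _plant_variants(
    config: CohortConfig,
    contigs: Mapping[str, str],
    genes: Sequence[GeneModel],
    contig_taxon: Mapping[str, str],
    rng: np.random.Generator,
):
    """Plant substitutions inside ORFs, away from coverage ramps.

    Positions stay at least ``read_length`` inside the gene (so DNA and RNA
    coverage is flat there) and at least :data:`MIN_VARIANT_SPACING_BP` apart
    within a gene (so no tryptic peptide spans two variants).
    """
    margin = config.read_length_bp
    planted: list[PlantedVariant] = []
    variant_proteins: dict[str, object] = {}
    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig, []).append(g)
    for taxon in config.taxa:
        slots: list[tuple[GeneModel, int]] = []
        taxon_genes = [
            g
            for c in contigs
            if contig_taxon[c] == taxon.genus
            for g in genes_by_contig.get(c, [])
        ]
        spacing = MIN_VARIANT_SPACING_BP + 30
        for g in taxon_genes:
            lo, hi = g.start + margin, g.end - margin
            p = lo
            while p <= hi:
                slots.append((g, p))
                p += spacing
        if config.variants_per_taxon > len(slots):
            raise ValueError(
                f"taxon {taxon.genus}: contigs cannot host {config.variants_per_taxon} "
                f"variants with {MIN_VARIANT_SPACING_BP} bp spacing ({len(slots)} slots)"
            )
        # spread variants across genes: round-robin over genes' slot lists
        by_gene: dict[str, list[tuple[GeneModel, int]]] = {}
        for g, p in slots:
            by_gene.setdefault(g.gene_id, []).append((g, p))
        ordered: list[tuple[GeneModel, int]] = []
        i = 0
        while len(ordered) < len(slots):
            for gid in sorted(by_gene):
                if i < len(by_gene[gid]):
                    ordered.append(by_gene[gid][i])
            i += 1
        for n, (gene, base_pos) in enumerate(ordered[: config.variants_per_taxon]):
            jitter = int(rng.integers(0, 30))
            pos = min(base_pos + jitter, gene.end - margin)
            contig_seq = contigs[gene.contig]
            ref = contig_seq[pos - 1]
            alt = rng.choice([b for b in BASES if b != ref])
            vid = f"{taxon.genus}_v{n + 1}"
            probe = VcfVariant(
                contig=gene.contig, pos_1based=pos, ref=ref, alt=alt,
                qual=0.0, depth=0, genotype=1, adf=(0, 0), adr=(0, 0),
            )
            effect, vp = annotate_variant_effect(probe, gene, contig_seq)
            planted.append(
                PlantedVariant(
                    variant_id=vid,
                    contig=gene.contig,
                    pos=pos,
                    ref=ref,
                    alt=str(alt),
                    genus=taxon.genus,
                    gene_id=gene.gene_id,
                    effect=effect,
                    present_in_oral=True,
                    present_in_gut=False,  # filled after transmission draws
                )
            )
            if vp is not None:
                variant_proteins[vid] = vp
    return planted, variant_proteins


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> CohortTruth:
    """Generate the cohort: genome, samples, planted variants, expression and
    peptide emissions.  Deterministic for a fixed ``config.seed``; writes the
    static cohort files when ``out_dir`` is given."""
    samples = _assign_conditions(config)
    rng_genome = _stream(config.seed, 0)
    contigs, genes, contig_taxon = _build_genome(config, rng_genome)
    planted, variant_proteins = _plant_variants(
        config, contigs, genes, contig_taxon, _stream(config.seed, 1)
    )

    individuals = sorted({s.individual for s in samples})
    condition = {s.individual: s.condition for s in samples}
    rng_trans = _stream(config.seed, 2)
    transmission: dict[tuple[str, str], bool] = {}
    for v in planted:
        for ind in individuals:
            p = config.transmission(v.genus, condition[ind])
            transmission[(v.variant_id, ind)] = bool(rng_trans.random() < p)
    planted = [
        PlantedVariant(
            **{
                **{f: getattr(v, f) for f in (
                    "variant_id", "contig", "pos", "ref", "alt", "genus", "gene_id",
                    "effect", "present_in_oral")},
                "present_in_gut": any(
                    transmission[(v.variant_id, ind)] for ind in individuals
                ),
            }
        )
        for v in planted
    ]

    rng_expr = _stream(config.seed, 3)
    expression: dict[str, float] = {}
    for g in genes:
        expressed = rng_expr.random() < config.expressed_gene_fraction
        rate = float(rng_expr.uniform(0.8, 1.5)) if expressed else 0.0
        expression[g.gene_id] = rate

    truth = CohortTruth(
        config=config,
        sample_table=samples,
        contigs=contigs,
        genes=genes,
        contig_taxon=contig_taxon,
        planted_variants=planted,
        transmission=transmission,
        expression_level=expression,
        emitted_peptides=[],
        variant_proteins=variant_proteins,
    )
    truth.emitted_peptides = _simulate_all_peptides(truth)
    if out_dir is not None:
        write_cohort(truth, out_dir)
    return truth


# ---------------------------------------------------------------------------
# alignment simulation
# ---------------------------------------------------------------------------


def simulate_alignments(truth: CohortTruth, sample: SampleMeta) -> list[ReadSet]:
    """Simulate all-match alignments for one DNA or RNA sample.

    DNA reads are placed uniformly along each contig with per-taxon coverage
    proportional to the site's abundance weight; RNA reads are placed within
    expressed ORFs with coverage proportional to the gene's expression rate.
    Reads overlapping a planted variant present at this sample's site carry
    the alternative base; bases are then flipped uniformly at the configured
    error rate.  Strands are balanced (Bernoulli 1/2 per read).
    """
    if sample not in truth.sample_table:
        raise ValueError(f"sample {sample.sample_id} does not belong to this cohort")
    if sample.ome == "MP":
        raise ValueError("alignments are simulated for MG/MT samples only")
    config = truth.config
    rng = _stream(config.seed, 4, sample.sample_id)
    R = config.read_length_bp
    e = config.base_error_rate
    qual = _phred(e)
    taxa = {t.genus: t for t in config.taxa}
    weights = [
        t.oral_abundance_weight if sample.site == "oral" else t.gut_abundance_weight
        for t in config.taxa
    ]
    mean_w = float(np.mean(weights)) if weights else 0.0

    out: list[ReadSet] = []
    for contig, seq in truth.contigs.items():
        taxon = taxa[truth.contig_taxon[contig]]
        w = taxon.oral_abundance_weight if sample.site == "oral" else taxon.gut_abundance_weight
        L = len(seq)
        codes = encode_seq(seq)
        present = [
            v for v in truth.variants_on(contig)
            if truth.is_present(v, sample.site, sample.individual)
        ]
        if sample.ome == "MG":
            if mean_w <= 0 or L < R:
                continue
            cov = config.coverage_dna * w / mean_w
            n = int(rng.poisson(2.0 * cov * (L - R + 1) / R))
            starts = rng.integers(1, L - R + 2, size=n, dtype=np.int64)
        else:  # MT: reads within expressed genes
            gene_reads = []
            for g in truth.genes:
                if g.contig != contig:
                    continue
                rate = truth.expression_level[g.gene_id]
                glen = len(g)
                if rate <= 0 or glen < R or mean_w <= 0:
                    continue
                cov = config.coverage_rna * rate * (w / mean_w)
                ng = int(rng.poisson(cov * (glen - R + 1) / R))
                gene_reads.append(
                    rng.integers(g.start, g.end - R + 2, size=ng, dtype=np.int64)
                )
            starts = (
                np.concatenate(gene_reads) if gene_reads else np.empty(0, dtype=np.int64)
            )
            n = len(starts)
        if n == 0:
            out.append(
                ReadSet(contig=contig, starts=np.empty(0, np.int64),
                        strands=np.empty(0, bool), seqs=np.empty((0, R), np.uint8),
                        qual_phred=qual, sample_id=sample.sample_id)
            )
            continue
        strands = rng.random(n) < 0.5
        seqs = codes[(starts[:, None] - 1) + np.arange(R)[None, :]]
        for v in present:
            mask = (starts <= v.pos) & (starts + R - 1 >= v.pos)
            if mask.any():
                seqs[mask, v.pos - starts[mask]] = BASES.index(v.alt)
        if e > 0:
            err = rng.random(seqs.shape) < e
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
                seqs[err] = (seqs[err] + shift) % 4
        out.append(
            ReadSet(
                contig=contig,
                starts=starts,
                strands=strands,
                seqs=seqs,
                qual_phred=qual,
                sample_id=sample.sample_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# peptide simulation
# ---------------------------------------------------------------------------


def _mutated_protein(truth: CohortTruth, gene: GeneModel, individual: str) -> tuple[str, list]:
    """Gut-strain protein of a gene for an individual: transmitted missense
    substitutions applied; returns (sequence, applied variant proteins)."""
    seq = protein_sequence(gene, truth.contigs[gene.contig])
    applied = []
    for v in truth.planted_variants:
        if v.gene_id != gene.gene_id or v.effect != "missense":
            continue
        if not truth.transmission[(v.variant_id, individual)]:
            continue
        vp = truth.variant_proteins[v.variant_id]
        idx = vp.variant_residue_index
        if idx <= len(seq):
            seq = seq[: idx - 1] + vp.alt_aa + seq[idx:]
        else:
            seq = seq + vp.alt_aa
        applied.append((v, vp))
    return seq, applied


def _simulate_all_peptides(truth: CohortTruth) -> list[EmittedPeptide]:
    config = truth.config
    if config.peptide_depth <= 0:
        return []
    reference = {
        g.gene_id: protein_sequence(g, truth.contigs[g.contig]) for g in truth.genes
    }
    ref_peps = reference_peptide_set(reference)
    taxa = {t.genus: t for t in config.taxa}
    gut_weights = [t.gut_abundance_weight for t in config.taxa]
    mean_w = float(np.mean(gut_weights)) if gut_weights else 0.0
    emitted: list[EmittedPeptide] = []
    mp_samples = [s for s in truth.sample_table if s.site == "gut" and s.ome == "MP"]
    for sample in mp_samples:
        rng = _stream(config.seed, 5, sample.sample_id)
        total = int(rng.poisson(config.peptide_depth))
        if total == 0:
            continue
        peptides: list[tuple[str, float, bool, tuple[str, ...]]] = []
        for g in truth.genes:
            rate = truth.expression_level[g.gene_id]
            if rate <= 0 or mean_w <= 0:
                continue
            w = taxa[truth.contig_taxon[g.contig]].gut_abundance_weight / mean_w
            protein, applied = _mutated_protein(truth, g, sample.individual)
            for pep, start, end in tryptic_digest(protein, missed_cleavages=0):
                vids = tuple(
                    v.variant_id
                    for v, vp in applied
                    if start <= vp.variant_residue_index <= end
                )
                is_var = bool(vids) and pep not in ref_peps
                peptides.append((pep, rate * w, is_var, vids if is_var else ()))
        if not peptides:
            continue
        probs = np.array([p[1] for p in peptides])
        probs /= probs.sum()
        counts = rng.multinomial(total, probs)
        for (pep, _w, is_var, vids), c in zip(peptides, counts):
            if c > 0:
                emitted.append(
                    EmittedPeptide(
                        sample_id=sample.sample_id,
                        peptide=pep,
                        is_variant_spanning=is_var,
                        variant_ids=vids,
                        count=int(c),
                    )
                )
    return emitted


def simulate_peptide_observations(truth: CohortTruth, sample: SampleMeta) -> pd.DataFrame:
    """Peptide observation table (sample_id, peptide, spectral_count) of one
    gut metaproteomic sample."""
    if sample.site != "gut" or sample.ome != "MP":
        raise ValueError("peptide observations exist for gut MP samples only")
    rows = [
        {"sample_id": p.sample_id, "peptide": p.peptide, "spectral_count": p.count}
        for p in truth.emitted_peptides
        if p.sample_id == sample.sample_id
    ]
    return pd.DataFrame(rows, columns=["sample_id", "peptide", "spectral_count"])


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_cohort(truth: CohortTruth, out_dir: str | Path) -> None:
    """Write the static cohort files: FASTA, GFF3, taxonomy, metadata,
    peptide table and the truth ledger TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.contigs, out / "contigs.fasta")
    write_gff(truth.genes, out / "genes.gff3")
    write_taxonomy(truth.contig_taxon, out / "taxonomy.tsv")
    write_metadata(truth.sample_table, out / "metadata.tsv")
    pep = pd.DataFrame(
        [
            {"sample_id": p.sample_id, "peptide": p.peptide, "spectral_count": p.count}
            for p in truth.emitted_peptides
        ],
        columns=["sample_id", "peptide", "spectral_count"],
    )
    write_peptides(pep, out / "peptides.tsv")
    pd.DataFrame(
        [
            {
                "variant_id": v.variant_id, "contig": v.contig, "pos": v.pos,
                "ref": v.ref, "alt": v.alt, "genus": v.genus, "gene_id": v.gene_id,
                "effect": v.effect, "present_in_oral": v.present_in_oral,
                "present_in_gut": v.present_in_gut,
            }
            for v in truth.planted_variants
        ]
    ).to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"variant_id": vid, "individual": ind, "transmitted": val}
            for (vid, ind), val in sorted(truth.transmission.items())
        ]
    ).to_csv(out / "truth_transmission.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "rate": r} for g, r in truth.expression_level.items()]
    ).to_csv(out / "truth_expression.tsv", sep="\t", index=False)


def write_sample_alignments(truth: CohortTruth, out_dir: str | Path) -> list[Path]:
    """Simulate and write a SAM file per MG/MT sample; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lengths = {c: len(s) for c, s in truth.contigs.items()}
    paths = []
    for sample in truth.sample_table:
        if sample.ome == "MP":
            continue
        readsets = simulate_alignments(truth, sample)
        path = out / f"{sample.sample_id}.sam"
        write_sam(readsets, path, lengths)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# abundance-level simulation for correlation analyses
# ---------------------------------------------------------------------------


def simulate_transfer_correlation_tables(
    n_samples: int,
    genera: Sequence[str],
    seed: int,
    noise_sigma: float = 0.25,
) -> dict[str, pd.DataFrame]:
    """Genus × sample abundance tables with a known dependence structure.

    Transfer abundance is a monotone function of gut abundance (power law
    with multiplicative log-normal noise) and independent of oral abundance —
    the structure under which transfer–gut correlations are real and
    transfer–oral correlations are null.
    """
    rng = np.random.default_rng([seed, 6])
    samples = [f"S{i + 1}" for i in range(n_samples)]
    gut = rng.lognormal(mean=3.0, sigma=1.0, size=(len(genera), n_samples))
    oral = rng.lognormal(mean=3.0, sigma=1.0, size=(len(genera), n_samples))
    transfer = gut ** 0.8 * rng.lognormal(mean=0.0, sigma=noise_sigma, size=gut.shape)
    make = lambda arr: pd.DataFrame(arr, index=list(genera), columns=samples)
    return {"gut": make(gut), "oral": make(oral), "transfer": make(transfer)}
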