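"""Cross-site, cross-omic support criteria for gut-contig variants.

A variant called on a gut contig is retained only when the oral community
carries the same alternative allele.  Two support classes are distinguished:

* ``MG_MT``: (i) positive alternative-allele depths on both strands in both
  gut DNA and oral DNA, and (ii) an alternative genotype (haploid GT = 1) in
  the oral DNA *and* the gut RNA — the variant is transferred and the gene is
  transcribed in the gut.
* ``MG_ONLY``: criterion (i) holds and the oral genotype is 1, but the
  gut-RNA clause fails (position uncovered by RNA or reference-like
  genotype).

Everything else is dropped.  Retained variants are annotated with their
coding effect and genus, quantified by read/spectral support per taxon, and
compared between conditions with the Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .formats import GeneModel, ReadSet, SampleMeta, VcfVariant, encode_seq, BASES
from .pileup import Pileup
from .proteogenomics import VariantPeptideHit, annotate_variant_effect, find_gene
from .stats import group_compare

LAYERS = ("MG", "MT", "MG_only", "MP")


@dataclass(frozen=True, slots=True)
class OmeEvidence:
    """Allelic evidence for one variant from one (site, ome) source."""

    source: tuple[str, str]  # (site, ome)
    adf: tuple[int, int]  # (ref_fwd, alt_fwd)
    adr: tuple[int, int]  # (ref_rev, alt_rev)
    genotype: int | None  # None when the position is uncovered
    present: bool


@dataclass(slots=True)
class TrackedVariant:
    """A gut-contig variant that passed the cross-site criteria."""

    site: VcfVariant
    evidence: dict[tuple[str, str], OmeEvidence]
    support_class: str  # "MG_MT" | "MG_ONLY"
    mp_supported: bool = False
    effect: str = "intergenic"
    genus: str = "unclassified"
    gene: GeneModel | None = None
    variant_protein: object | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.site.key


class ReadAssignment(NamedTuple):
    """One read carrying the alternative allele of one tracked variant."""

    read_id: str
    source: tuple  # caller-defined source key, e.g. (sample_id, site, ome)
    variant_key: tuple[str, int, str, str]


@dataclass
class TransferSummary:
    """Per-taxon transfer quantification.

    ``per_sample``: one row per (genus, sample, layer) with the number of
    distinct variants and the read/spectral support observed in that sample.
    ``per_genus``: per (genus, layer) totals with the number of samples in
    which variants were identified and the median number of variants per
    such sample.
    """

    per_sample: pd.DataFrame
    per_genus: pd.DataFrame


def _evidence(pileup: Pileup | None, v: VcfVariant, source: tuple[str, str],
              gt_alt_fraction: float) -> OmeEvidence:
    if pileup is None:
        return OmeEvidence(source=source, adf=(0, 0), adr=(0, 0), genotype=None, present=False)
    adf, adr = pileup.allele_depths(v.pos_1based, v.ref, v.alt)
    gt = pileup.genotype(v.pos_1based, v.ref, v.alt, gt_alt_fraction)
    present = (adf[1] + adr[1]) > 0
    return OmeEvidence(source=source, adf=adf, adr=adr, genotype=gt, present=present)


def evaluate_cross_site_criteria(
    gut_variants: Sequence[VcfVariant],
    oral_dna_pileup: Mapping[str, Pileup],
    gut_dna_pileup: Mapping[str, Pileup],
    gut_rna_pileup: Mapping[str, Pileup],
    gt_alt_fraction: float = 0.5,
    gene_models: Sequence[GeneModel] | None = None,
    contigs: Mapping[str, str] | None = None,
    taxonomy: Mapping[str, str] | None = None,
) -> list[TrackedVariant]:
    """Apply the transfer criteria to variants called on gut contigs.

    The oral and gut DNA pileups must cover every contig with a variant;
    a contig absent from the RNA pileup map counts as uncovered (the variant
    can still be retained as MG_ONLY).  When gene models and contigs are
    given, the retained variants are annotated with their coding effect;
    with a taxonomy map, with their genus.
    """
    tracked: list[TrackedVariant] = []
    for v in gut_variants:
        for name, pmap in (("oral DNA", oral_dna_pileup), ("gut DNA", gut_dna_pileup)):
            if v.contig not in pmap:
                raise ValueError(f"{name} pileup is missing contig {v.contig}")
        ev_gut = _evidence(gut_dna_pileup[v.contig], v, ("gut", "MG"), gt_alt_fraction)
        ev_oral = _evidence(oral_dna_pileup[v.contig], v, ("oral", "MG"), gt_alt_fraction)
        ev_rna = _evidence(gut_rna_pileup.get(v.contig), v, ("gut", "MT"), gt_alt_fraction)

        # (i) positive alt depths on both strands in gut DNA and oral DNA
        crit_i = (
            ev_gut.adf[1] > 0 and ev_gut.adr[1] > 0
            and ev_oral.adf[1] > 0 and ev_oral.adr[1] > 0
        )
        if not crit_i or ev_oral.genotype != 1:
            continue
        support = "MG_MT" if ev_rna.genotype == 1 else "MG_ONLY"
        tv = TrackedVariant(
            site=v,
            evidence={e.source: e for e in (ev_gut, ev_oral, ev_rna)},
            support_class=support,
        )
        if gene_models is not None and contigs is not None:
            gene = find_gene(gene_models, v.contig, v.pos_1based)
            effect, vp = annotate_variant_effect(v, gene, contigs[v.contig])
            tv.effect, tv.gene, tv.variant_protein = effect, gene, vp
        if taxonomy is not None:
            tv.genus = taxonomy.get(v.contig, "unclassified")
        tracked.append(tv)
    return tracked


def extract_variant_reads(
    alignments_by_source: Mapping[tuple, Sequence[ReadSet]],
    tracked: Sequence[TrackedVariant],
) -> list[ReadAssignment]:
    """Assign alt-carrying reads to tracked variants.

    A read is assigned to a variant iff its alignment covers the variant
    position and carries the alternative base there; a read covering k
    variants yields k assignments.
    """
    by_contig: dict[str, list[TrackedVariant]] = {}
    for tv in tracked:
        by_contig.setdefault(tv.site.contig, []).append(tv)
    out: list[ReadAssignment] = []
    for source, readsets in alignments_by_source.items():
        for rs in readsets:
            variants = by_contig.get(rs.contig)
            if not variants or len(rs) == 0:
                continue
            R = rs.read_length
            ids = None
            for tv in variants:
                pos, alt = tv.site.pos_1based, tv.site.alt
                mask = (rs.starts <= pos) & (rs.starts + R - 1 >= pos)
                if not mask.any():
                    continue
                cols = pos - rs.starts[mask]
                hit = rs.seqs[mask, cols] == BASES.index(alt)
                if not hit.any():
                    continue
                if ids is None:
                    ids = rs.ids
                idx = np.flatnonzero(mask)[hit]
                out.extend(
                    ReadAssignment(read_id=ids[i], source=source, variant_key=tv.key)
                    for i in idx
                )
    return out


def taxon_variant_abundance(
    assignments: Sequence[ReadAssignment],
    mp_hits: Sequence[VariantPeptideHit],
    contig_to_genus: Mapping[str, str],
    tracked: Sequence[TrackedVariant],
    class_by_sample: Mapping[tuple[str, tuple], str] | None = None,
) -> TransferSummary:
    """Aggregate variant read/spectral support per (genus, sample, layer).

    Layers: ``MG`` (gut DNA reads of MG_MT variants), ``MT`` (gut RNA reads
    of MG_MT variants), ``MG_only`` (gut DNA reads of MG_ONLY variants) and
    ``MP`` (spectral counts of variant peptide hits).  Oral-source
    assignments are not part of the gut abundance summary.  Assignment
    sources must be (sample_id, site, ome) tuples.  When the support class
    of a variant differs between samples (RNA coverage varies), pass
    ``class_by_sample`` mapping (sample_id, variant key) → class; it takes
    precedence over the cohort-wide class of ``tracked``.
    """
    class_of = {tv.key: tv.support_class for tv in tracked}
    genus_of = {tv.key: contig_to_genus.get(tv.site.contig, "unclassified") for tv in tracked}
    rows: dict[tuple[str, str, str], dict] = {}

    def bump(genus: str, sample: str, layer: str, variant, n: int) -> None:
        row = rows.setdefault(
            (genus, sample, layer),
            {"variants": set(), "n_reads_or_spectra": 0},
        )
        row["variants"].add(variant)
        row["n_reads_or_spectra"] += n

    for a in assignments:
        sample_id, site, ome = a.source
        if site != "gut":
            continue
        cls = None
        if class_by_sample is not None:
            cls = class_by_sample.get((sample_id, a.variant_key))
        if cls is None:
            cls = class_of.get(a.variant_key)
        if cls is None:
            continue
        if ome == "MG":
            layer = "MG" if cls == "MG_MT" else "MG_only"
        elif ome == "MT":
            if cls != "MG_MT":
                continue
            layer = "MT"
        else:
            continue
        bump(genus_of[a.variant_key], sample_id, layer, a.variant_key, 1)

    tv_by_pid = {}
    for tv in tracked:
        if tv.variant_protein is not None:
            tv_by_pid[tv.variant_protein.protein_id] = tv
    for hit in mp_hits:
        tv = hit.variant if hit.variant is not None else tv_by_pid.get(hit.protein_id)
        if tv is None:
            continue
        bump(genus_of.get(tv.key, "unclassified"), hit.sample, "MP", tv.key, hit.spectral_count)

    per_sample = pd.DataFrame(
        [
            {
                "genus": g, "sample": s, "layer": layer,
                "n_variants": len(row["variants"]),
                "n_reads_or_spectra": row["n_reads_or_spectra"],
            }
            for (g, s, layer), row in sorted(rows.items())
        ],
        columns=["genus", "sample", "layer", "n_variants", "n_reads_or_spectra"],
    )
    genus_rows = []
    if len(per_sample):
        for (g, layer), grp in per_sample.groupby(["genus", "layer"]):
            variant_union = set()
            for key in rows:
                if key[0] == g and key[2] == layer:
                    variant_union |= rows[key]["variants"]
            genus_rows.append(
                {
                    "genus": g,
                    "layer": layer,
                    "n_variants": len(variant_union),
                    "n_samples_with_variants": grp["sample"].nunique(),
                    "median_variants_per_sample": float(grp["n_variants"].median()),
                    "n_reads_or_spectra": int(grp["n_reads_or_spectra"].sum()),
                }
            )
    per_genus = pd.DataFrame(
        genus_rows,
        columns=[
            "genus", "layer", "n_variants", "n_samples_with_variants",
            "median_variants_per_sample", "n_reads_or_spectra",
        ],
    )
    return TransferSummary(per_sample=per_sample, per_genus=per_genus)


def compare_transfer_by_condition(
    summary: TransferSummary,
    metadata: Sequence[SampleMeta],
    layers: Sequence[str] = LAYERS,
) -> pd.DataFrame:
    """Mann–Whitney U comparison of per-sample variant support, T1DM vs
    control, per (genus, layer).

    Gut samples of the layer's ome with no observed variant support
    contribute zeros, so the comparison covers the whole cohort and not only
    samples with detections.  Rows with fewer than two samples in either
    condition are flagged not testable.
    """
    layer_ome = {"MG": "MG", "MG_only": "MG", "MT": "MT", "MP": "MP"}
    rows = []
    per_sample = summary.per_sample
    for layer in layers:
        ome = layer_ome[layer]
        cohort = [s for s in metadata if s.site == "gut" and s.ome == ome]
        if not cohort:
            continue
        sub = per_sample[per_sample["layer"] == layer]
        for genus in sorted(sub["genus"].unique()) if len(sub) else []:
            counts = dict(
                zip(
                    sub[sub["genus"] == genus]["sample"],
                    sub[sub["genus"] == genus]["n_reads_or_spectra"],
                )
            )
            values = {"T1DM": [], "control": []}
            for s in cohort:
                values[s.condition].append(float(counts.get(s.sample_id, 0)))
            res = group_compare(values["T1DM"], values["control"])
            rows.append(
                {
                    "genus": genus,
                    "layer": layer,
                    "n_t1dm": len(values["T1DM"]),
                    "n_control": len(values["control"]),
                    "U": res.U,
                    "p_value": res.p,
                    "testable": res.testable,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["genus", "layer", "n_t1dm", "n_control", "U", "p_value", "testable"],
    )
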