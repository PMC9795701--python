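"""End-to-end transmission analysis on a synthetic cohort.

Runs the whole pipeline in memory: simulate per-sample alignments, pool the
oral DNA reads of an individual across visits, call variants on the gut
contigs per gut sample, apply the cross-site support criteria with the
matched gut-RNA pileup, extract alt-carrying reads, confer metaproteomic
support via variant-peptide matching, and aggregate the per-taxon transfer
summary with condition comparisons.  Also provides the truth-ledger scoring
used to validate recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import SampleMeta
from .pileup import CallParams, Pileup, call_variants, pileup_counts
from .proteogenomics import (
    build_search_database,
    match_variant_peptides,
    protein_sequence,
)
from .synthetic import CohortTruth, simulate_alignments, simulate_peptide_observations
from .tracking import (
    ReadAssignment,
    TrackedVariant,
    TransferSummary,
    compare_transfer_by_condition,
    evaluate_cross_site_criteria,
    extract_variant_reads,
    taxon_variant_abundance,
)


@dataclass
class TransmissionResult:
    """Everything the end-to-end analysis produces."""

    tracked_by_sample: dict[str, list[TrackedVariant]]  # gut MG sample -> variants
    assignments: list[ReadAssignment]
    mp_hits: list
    summary: TransferSummary
    comparisons: pd.DataFrame
    params: CallParams


def _derive_error_rate(readsets) -> float:
    """Sequencing error rate implied by the reads' constant base quality."""
    for rs in readsets:
        if len(rs):
            return max(10.0 ** (-rs.qual_phred / 10.0), 1e-10)
    return 1e-4


def run_transmission_analysis(
    truth: CohortTruth,
    params: CallParams | None = None,
    with_mp: bool = True,
) -> TransmissionResult:
    """Run the full mouth-to-gut variant tracking pipeline on a cohort.

    Oral DNA evidence is pooled across an individual's visits before the
    criteria are evaluated; gut DNA/RNA evidence is per visit.  When
    ``params`` is None, calling thresholds use the defaults and the error
    rate implied by the simulated base qualities.
    """
    cfg = truth.config
    contigs = truth.contigs
    lengths = {c: len(s) for c, s in contigs.items()}
    genes = truth.genes
    taxonomy = truth.contig_taxon
    reference_proteome = {
        g.gene_id: protein_sequence(g, contigs[g.contig]) for g in genes
    }
    visits = range(1, cfg.visits_per_individual + 1)

    tracked_by_sample: dict[str, list[TrackedVariant]] = {}
    class_by_sample: dict[tuple[str, tuple], str] = {}
    assignments: list[ReadAssignment] = []
    mp_hits_all: list = []
    all_tracked: list[TrackedVariant] = []
    used_params: CallParams | None = params

    for ind in truth.individuals:
        # pooled oral DNA evidence across all available visits
        oral_by_contig: dict[str, list] = {}
        for v in visits:
            s_oral = truth.sample(ind, v, "oral", "MG")
            for rs in simulate_alignments(truth, s_oral):
                oral_by_contig.setdefault(rs.contig, []).append(rs)
        oral_pileups = {
            c: pileup_counts(
                oral_by_contig.get(c, []), c, lengths[c],
                (params or CallParams()).max_depth,
            )
            for c in contigs
        }
        oral_flat = [rs for lst in oral_by_contig.values() for rs in lst]
        oral_source = (f"{ind}_oral_MG_pooled", "oral", "MG")
        union_by_key: dict[tuple, TrackedVariant] = {}

        for v in visits:
            s_mg = truth.sample(ind, v, "gut", "MG")
            s_mt = truth.sample(ind, v, "gut", "MT")
            gut_sets = simulate_alignments(truth, s_mg)
            rna_sets = simulate_alignments(truth, s_mt)
            p = params or CallParams(error_rate=_derive_error_rate(gut_sets))
            used_params = p
            gut_pileups = {
                rs.contig: pileup_counts([rs], rs.contig, lengths[rs.contig], p.max_depth)
                for rs in gut_sets
            }
            rna_pileups = {
                rs.contig: pileup_counts([rs], rs.contig, lengths[rs.contig], p.max_depth)
                for rs in rna_sets
            }
            variants = []
            for c, pile in gut_pileups.items():
                variants.extend(call_variants(pile, contigs[c], p))
            tracked = evaluate_cross_site_criteria(
                variants, oral_pileups, gut_pileups, rna_pileups,
                gt_alt_fraction=p.gt_alt_fraction,
                gene_models=genes, contigs=contigs, taxonomy=taxonomy,
            )
            tracked_by_sample[s_mg.sample_id] = tracked
            all_tracked.extend(tracked)
            for tv in tracked:
                class_by_sample[(s_mg.sample_id, tv.key)] = tv.support_class
                class_by_sample[(s_mt.sample_id, tv.key)] = tv.support_class
                union_by_key.setdefault(tv.key, tv)
            assignments.extend(
                extract_variant_reads(
                    {
                        (s_mg.sample_id, "gut", "MG"): gut_sets,
                        (s_mt.sample_id, "gut", "MT"): rna_sets,
                    },
                    tracked,
                )
            )
            if with_mp:
                s_mp = truth.sample(ind, v, "gut", "MP")
                observed = simulate_peptide_observations(truth, s_mp)
                vps = [tv.variant_protein for tv in tracked if tv.variant_protein is not None]
                if len(observed) and vps:
                    db = build_search_database(reference_proteome, vps)
                    hits = match_variant_peptides(observed, db, vps, reference_proteome)
                    pid_to_tv = {
                        tv.variant_protein.protein_id: tv
                        for tv in tracked
                        if tv.variant_protein is not None
                    }
                    for h in hits:
                        tv = pid_to_tv.get(h.protein_id)
                        if tv is not None:
                            h.variant = tv
                            tv.mp_supported = True
                    mp_hits_all.extend(hits)
        if union_by_key:
            assignments.extend(
                extract_variant_reads(
                    {oral_source: oral_flat}, list(union_by_key.values())
                )
            )

    summary = taxon_variant_abundance(
        assignments, mp_hits_all, taxonomy, all_tracked, class_by_sample
    )
    comparisons = compare_transfer_by_condition(summary, truth.sample_table)
    return TransmissionResult(
        tracked_by_sample=tracked_by_sample,
        assignments=assignments,
        mp_hits=mp_hits_all,
        summary=summary,
        comparisons=comparisons,
        params=used_params or CallParams(),
    )


# ---------------------------------------------------------------------------
# truth-ledger scoring
# ---------------------------------------------------------------------------


def evaluate_against_truth(result: TransmissionResult, truth: CohortTruth) -> dict:
    """Score the pipeline's retained variants against the planted truth.

    Returns sensitivity and false-positive fraction of transmitted-variant
    detection, the MG_MT/MG_ONLY class accuracy against the expression
    ledger, and the metaproteomic support recovery among transmitted
    missense variants whose variant-spanning peptides were actually emitted.
    """
    expression = truth.expression_level
    gene_of = {v.key: v.gene_id for v in truth.planted_variants}
    vid_of = {v.key: v.variant_id for v in truth.planted_variants}
    by_vid = {v.variant_id: v for v in truth.planted_variants}

    n_expected = n_tp = n_retained = n_labels_ok = 0
    mp_eligible = mp_supported = 0
    for sample_id, tracked in result.tracked_by_sample.items():
        meta = next(s for s in truth.sample_table if s.sample_id == sample_id)
        ind, visit = meta.individual, meta.visit
        expected = {
            v.key for v in truth.planted_variants
            if truth.transmission[(v.variant_id, ind)]
        }
        detected = {tv.key: tv for tv in tracked}
        n_expected += len(expected)
        n_retained += len(detected)
        tps = expected & set(detected)
        n_tp += len(tps)
        for key in tps:
            want = "MG_MT" if expression[gene_of[key]] > 0 else "MG_ONLY"
            if detected[key].support_class == want:
                n_labels_ok += 1
        # MP recovery: transmitted missense variants whose variant-spanning
        # peptides were emitted in this visit's MP sample
        mp_sample = truth.sample(ind, visit, "gut", "MP").sample_id
        emitted_vids = {
            vid
            for p in truth.emitted_peptides
            if p.sample_id == mp_sample and p.is_variant_spanning
            for vid in p.variant_ids
        }
        for vid in emitted_vids:
            v = by_vid[vid]
            if v.effect != "missense" or not truth.transmission[(vid, ind)]:
                continue
            if v.key not in detected:
                continue
            mp_eligible += 1
            if detected[v.key].mp_supported:
                mp_supported += 1

    return {
        "n_expected": n_expected,
        "n_retained": n_retained,
        "n_true_positive": n_tp,
        "sensitivity": n_tp / n_expected if n_expected else float("nan"),
        "false_positive_rate": (n_retained - n_tp) / n_retained if n_retained else 0.0,
        "label_accuracy": n_labels_ok / n_tp if n_tp else float("nan"),
        "mp_eligible": mp_eligible,
        "mp_support_rate": mp_supported / mp_eligible if mp_eligible else float("nan"),
    }


def gut_variant_reads_by_condition(
    result: TransmissionResult,
    truth: CohortTruth,
    genus: str,
    layers: tuple[str, ...] = ("MG", "MG_only"),
) -> tuple[list[float], list[float]]:
    """Per-sample gut-DNA variant-read counts for one genus, split by
    condition (T1DM first).  Gut MG samples without detections contribute 0.
    """
    per_sample = result.summary.per_sample
    sub = per_sample[(per_sample["genus"] == genus) & per_sample["layer"].isin(layers)]
    counts = sub.groupby("sample")["n_reads_or_spectra"].sum().to_dict()
    t1dm, control = [], []
    for s in truth.sample_table:
        if s.site != "gut" or s.ome != "MG":
            continue
        (t1dm if s.condition == "T1DM" else control).append(float(counts.get(s.sample_id, 0)))
    return t1dm, control
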