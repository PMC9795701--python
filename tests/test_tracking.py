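"""Cross-site support criteria, read extraction and transfer summaries."""

import numpy as np
import pytest

from straintrace.formats import BASES, ReadSet, SampleMeta, VcfVariant, encode_seq
from straintrace.pileup import Pileup
from straintrace.proteogenomics import VariantPeptideHit, VariantProtein
from straintrace.tracking import (
    ReadAssignment,
    compare_transfer_by_condition,
    evaluate_cross_site_criteria,
    extract_variant_reads,
    taxon_variant_abundance,
)


def make_pileup(contig, length, spec):
    """Pileup from {pos: {(base, 'fwd'|'rev'): count}}."""
    counts = np.zeros((length, 4, 2), dtype=np.int64)
    for pos, alleles in spec.items():
        for (base, strand), n in alleles.items():
            counts[pos - 1, BASES.index(base), 0 if strand == "fwd" else 1] = n
    return Pileup(contig, counts)


def gut_variant(pos=10, ref="A", alt="G", gt=1):
    return VcfVariant(
        contig="c1", pos_1based=pos, ref=ref, alt=alt, qual=40.0, depth=20,
        genotype=gt, adf=(2, 6), adr=(2, 6),
    )


def _pileups(oral=None, gut=None, rna=None, pos=10):
    """Default evidence: clean alt on both strands everywhere, GT=1."""
    default_oral = {pos: {("G", "fwd"): 3, ("G", "rev"): 2}}
    default_gut = {pos: {("G", "fwd"): 4, ("G", "rev"): 4, ("A", "fwd"): 1}}
    default_rna = {pos: {("G", "fwd"): 5, ("G", "rev"): 4}}
    return (
        {"c1": make_pileup("c1", 50, oral if oral is not None else default_oral)},
        {"c1": make_pileup("c1", 50, gut if gut is not None else default_gut)},
        {"c1": make_pileup("c1", 50, rna if rna is not None else default_rna)},
    )


class TestCrossSiteCriteria:
    def test_full_support_is_mg_mt(self):
        oral, gut, rna = _pileups()
        (tv,) = evaluate_cross_site_criteria([gut_variant()], oral, gut, rna)
        assert tv.support_class == "MG_MT"
        assert tv.evidence[("oral", "MG")].genotype == 1
        assert tv.evidence[("gut", "MT")].genotype == 1

    def test_missing_oral_reverse_strand_depth_drops_variant(self):
        oral, gut, rna = _pileups(oral={10: {("G", "fwd"): 5}})
        assert evaluate_cross_site_criteria([gut_variant()], oral, gut, rna) == []

    def test_missing_gut_forward_strand_depth_drops_variant(self):
        oral, gut, rna = _pileups(gut={10: {("G", "rev"): 9, ("A", "fwd"): 1}})
        assert evaluate_cross_site_criteria([gut_variant()], oral, gut, rna) == []

    def test_single_read_per_strand_satisfies_criterion_i(self):
        oral, gut, rna = _pileups(
            oral={10: {("G", "fwd"): 1, ("G", "rev"): 1}},
            gut={10: {("G", "fwd"): 1, ("G", "rev"): 1}},
        )
        (tv,) = evaluate_cross_site_criteria([gut_variant()], oral, gut, rna)
        assert tv.support_class == "MG_MT"

    def test_oral_reference_genotype_drops_variant(self):
        oral, gut, rna = _pileups(
            oral={10: {("G", "fwd"): 1, ("G", "rev"): 1, ("A", "fwd"): 8, ("A", "rev"): 8}}
        )
        assert evaluate_cross_site_criteria([gut_variant()], oral, gut, rna) == []

    def test_uncovered_rna_position_gives_mg_only(self):
        oral, gut, rna = _pileups(rna={})
        (tv,) = evaluate_cross_site_criteria([gut_variant()], oral, gut, rna)
        assert tv.support_class == "MG_ONLY"
        assert tv.evidence[("gut", "MT")].genotype is None

    def test_contig_absent_from_rna_map_gives_mg_only(self):
        oral, gut, _ = _pileups()
        (tv,) = evaluate_cross_site_criteria([gut_variant()], oral, gut, {})
        assert tv.support_class == "MG_ONLY"

    def test_reference_like_rna_genotype_gives_mg_only(self):
        oral, gut, rna = _pileups(rna={10: {("A", "fwd"): 9, ("G", "rev"): 1}})
        (tv,) = evaluate_cross_site_criteria([gut_variant()], oral, gut, rna)
        assert tv.support_class == "MG_ONLY"

    def test_classes_are_disjoint_and_exhaustive(self, rng):
        variants = [gut_variant()]
        for _ in range(200):
            def rand_spec():
                return {
                    10: {
                        ("G", "fwd"): int(rng.integers(0, 4)),
                        ("G", "rev"): int(rng.integers(0, 4)),
                        ("A", "fwd"): int(rng.integers(0, 4)),
                        ("A", "rev"): int(rng.integers(0, 4)),
                    }
                }
            oral, gut, rna = _pileups(rand_spec(), rand_spec(), rand_spec())
            tracked = evaluate_cross_site_criteria(variants, oral, gut, rna)
            assert len(tracked) <= 1
            for tv in tracked:
                assert tv.support_class in ("MG_MT", "MG_ONLY")
                ev_o = tv.evidence[("oral", "MG")]
                ev_g = tv.evidence[("gut", "MG")]
                assert ev_o.adf[1] > 0 and ev_o.adr[1] > 0
                assert ev_g.adf[1] > 0 and ev_g.adr[1] > 0
                assert ev_o.genotype == 1
                rna_gt = tv.evidence[("gut", "MT")].genotype
                assert (tv.support_class == "MG_MT") == (rna_gt == 1)

    def test_missing_dna_contig_is_an_error(self):
        oral, gut, rna = _pileups()
        with pytest.raises(ValueError, match="c1"):
            evaluate_cross_site_criteria([gut_variant()], {}, gut, rna)


def _readset(contig, starts, seq_strings, sample="s1"):
    return ReadSet(
        contig=contig,
        starts=np.array(starts, dtype=np.int64),
        strands=np.ones(len(starts), dtype=bool),
        seqs=np.vstack([encode_seq(s) for s in seq_strings]),
        qual_phred=40,
        sample_id=sample,
        read_ids=[f"{sample}:r{i}" for i in range(len(starts))],
    )


class TestExtractVariantReads:
    def _tracked(self, *variants):
        from straintrace.tracking import TrackedVariant

        out = []
        for v in variants:
            out.append(
                TrackedVariant(site=v, evidence={}, support_class="MG_MT")
            )
        return out

    def test_reference_read_not_assigned(self):
        tracked = self._tracked(gut_variant(pos=3))
        rs = _readset("c1", [1], ["AAAAA"])
        assert extract_variant_reads({("s1", "gut", "MG"): [rs]}, tracked) == []

    def test_read_covering_two_variants_yields_two_assignments(self):
        v1 = gut_variant(pos=3)
        v2 = gut_variant(pos=5, ref="A", alt="T")
        tracked = self._tracked(v1, v2)
        rs = _readset("c1", [1], ["AAGAT"])
        got = extract_variant_reads({("s1", "gut", "MG"): [rs]}, tracked)
        assert {a.variant_key for a in got} == {v1.key, v2.key}
        assert all(a.read_id == "s1:r0" for a in got)

    def test_five_alt_reads_give_five_assignments(self):
        tracked = self._tracked(gut_variant(pos=3))
        rs = _readset("c1", [1] * 5 + [1], ["AAGAA"] * 5 + ["AAAAA"], sample="oral1")
        got = extract_variant_reads({("ind1", "oral", "MG"): [rs]}, tracked)
        assert len(got) == 5
        assert all(a.source == ("ind1", "oral", "MG") for a in got)

    def test_counts_match_brute_force_scan(self, rng):
        v = gut_variant(pos=25, ref="A", alt="G")
        tracked = self._tracked(v)
        n = 200
        starts = rng.integers(1, 41, size=n)
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, size=10)) for _ in range(n)]
        rs = _readset("c1", list(starts), seqs)
        got = extract_variant_reads({("s1", "gut", "MG"): [rs]}, tracked)
        expected = sum(
            1
            for start, seq in zip(starts, seqs)
            if start <= 25 <= start + 9 and seq[25 - start] == "G"
        )
        assert len(got) == expected


def _mk_tracked(contig, pos, support, genus="Prevotella", ref="A", alt="G"):
    from straintrace.tracking import TrackedVariant

    v = VcfVariant(
        contig=contig, pos_1based=pos, ref=ref, alt=alt, qual=40.0, depth=20,
        genotype=1, adf=(2, 6), adr=(2, 6),
    )
    return TrackedVariant(site=v, evidence={}, support_class=support, genus=genus)


class TestTransferSummary:
    def test_no_assignments_gives_empty_summary(self):
        summary = taxon_variant_abundance([], [], {}, [])
        assert len(summary.per_sample) == 0 and len(summary.per_genus) == 0

    def test_taxonomy_pass_through(self):
        tv = _mk_tracked("p_c1", 10, "MG_MT")
        assignments = [
            ReadAssignment("r1", ("s1", "gut", "MG"), tv.key),
            ReadAssignment("r2", ("s1", "gut", "MG"), tv.key),
        ]
        summary = taxon_variant_abundance(assignments, [], {"p_c1": "Prevotella"}, [tv])
        assert set(summary.per_sample["genus"]) == {"Prevotella"}
        row = summary.per_sample.iloc[0]
        assert row["layer"] == "MG" and row["n_reads_or_spectra"] == 2

    def test_mg_only_variants_counted_in_their_own_layer(self):
        tv = _mk_tracked("p_c1", 10, "MG_ONLY")
        assignments = [ReadAssignment("r1", ("s1", "gut", "MG"), tv.key)]
        summary = taxon_variant_abundance(assignments, [], {"p_c1": "Prevotella"}, [tv])
        assert list(summary.per_sample["layer"]) == ["MG_only"]

    def test_oral_assignments_excluded_from_gut_summary(self):
        tv = _mk_tracked("p_c1", 10, "MG_MT")
        assignments = [ReadAssignment("r1", ("i1", "oral", "MG"), tv.key)]
        summary = taxon_variant_abundance(assignments, [], {"p_c1": "Prevotella"}, [tv])
        assert len(summary.per_sample) == 0

    def test_median_variants_per_sample(self):
        tvs = [_mk_tracked("p_c1", 10 + i, "MG_MT") for i in range(6)]
        assignments = []
        for sample, n in (("s1", 2), ("s2", 4), ("s3", 6)):
            for i in range(n):
                assignments.append(
                    ReadAssignment(f"{sample}:r{i}", (sample, "gut", "MG"), tvs[i].key)
                )
        summary = taxon_variant_abundance(assignments, [], {"p_c1": "Prevotella"}, tvs)
        row = summary.per_genus.iloc[0]
        assert row["n_samples_with_variants"] == 3
        assert row["median_variants_per_sample"] == 4.0

    def test_mp_hits_counted_as_spectra(self):
        tv = _mk_tracked("p_c1", 10, "MG_MT")
        tv.variant_protein = VariantProtein("vp1", "ME" + "A" * 70, 2, "K", "E")
        hit = VariantPeptideHit(
            peptide="MEAAAAK", protein_id="vp1", sample="s1_MP", spectral_count=3,
            variant=tv,
        )
        summary = taxon_variant_abundance([], [hit], {"p_c1": "Prevotella"}, [tv])
        row = summary.per_sample.iloc[0]
        assert row["layer"] == "MP" and row["n_reads_or_spectra"] == 3


class TestConditionComparison:
    def _metadata(self, n_per_group=10):
        rows = []
        for i in range(n_per_group * 2):
            cond = "T1DM" if i < n_per_group else "control"
            rows.append(
                SampleMeta(f"s{i}_gut_MG", f"I{i}", f"F{i % 4}", 1, cond, "gut", "MG")
            )
        return rows

    def _summary(self, counts_by_sample):
        import pandas as pd

        from straintrace.tracking import TransferSummary

        per_sample = pd.DataFrame(
            [
                {
                    "genus": "Prevotella", "sample": s, "layer": "MG",
                    "n_variants": 1, "n_reads_or_spectra": c,
                }
                for s, c in counts_by_sample.items()
            ]
        )
        return TransferSummary(per_sample=per_sample, per_genus=pd.DataFrame())

    def test_identical_distributions_not_significant(self):
        meta = self._metadata()
        counts = {s.sample_id: 5 for s in meta}
        df = compare_transfer_by_condition(self._summary(counts), meta, layers=("MG",))
        assert df.iloc[0]["p_value"] > 0.05

    def test_disjoint_distributions_are_extreme(self):
        meta = self._metadata(10)
        counts = {
            s.sample_id: (0 if s.condition == "T1DM" else 10 + i)
            for i, s in enumerate(meta)
        }
        df = compare_transfer_by_condition(self._summary(counts), meta, layers=("MG",))
        row = df.iloc[0]
        assert row["p_value"] < 0.01 and row["testable"]

    def test_single_condition_cohort_flagged_not_testable(self):
        meta = [
            SampleMeta("s0_gut_MG", "I0", "F0", 1, "control", "gut", "MG"),
            SampleMeta("s1_gut_MG", "I1", "F0", 1, "control", "gut", "MG"),
        ]
        df = compare_transfer_by_condition(
            self._summary({"s0_gut_MG": 3, "s1_gut_MG": 4}), meta, layers=("MG",)
        )
        assert not df.iloc[0]["testable"]
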