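# straintrace

Strain-resolved tracking of microbial variants from the oral cavity to the
gut, integrated across metagenomic (MG), metatranscriptomic (MT) and
metaproteomic (MP) data.

## The problem

The mouth seeds the rest of the gastrointestinal tract: a subset of oral
bacteria survive passage and colonise the gut.  Because assembly collapses
co-occurring strains into consensus contigs, transfer is invisible at the
species level — but it can be recovered from *strain variants*: substitution
alleles that distinguish conspecific strains.  A variant called on a gut
contig that is also carried by the oral community of the same individual is
evidence of mouth-to-gut transmission; RNA and peptide support for the same
allele shows that the transmitted strain is also active in the gut.  This
matters in disease cohorts (for example families with type 1 diabetes
mellitus, T1DM) where altered oral physiology can change what is transmitted.

`straintrace` implements this analysis as a tested pipeline, together with a
synthetic family-structured cohort generator so that every stage can be
validated against a ground-truth ledger without any external data.

## Method

1. **Pileup and calling.**  Strand-resolved allele depths are counted from
   all-match alignments of gut DNA reads against gut contigs (per-position
   depth capped at 1000).  At each site the majority non-reference base is
   scored with a binomial-tail Phred quality,
   `QUAL = −10·log₁₀ P(X ≥ n_alt)` with `X ~ Binomial(n_ref + n_alt, e)`,
   and a variant is emitted when `QUAL ≥ 20` and used depth `≥ 10` (indels
   are out of scope).  The haploid genotype is `1` when the alternative
   allele reaches half the allelic depth.
2. **Cross-site criteria.**  A gut variant is retained only if
   (i) the alternative allele has positive depth on **both** strands in both
   the gut DNA and the (visit-pooled) oral DNA of the same individual, and
   the oral genotype is `1`; it is classed **MG-MT supported** when the gut
   RNA genotype at that position is also `1`, and **MG-only supported** when
   the RNA clause fails (uncovered or reference-like).
3. **Proteogenomic support.**  Missense variants (located by codon against
   the gene models, standard genetic code) yield single-substitution variant
   proteins.  Search databases are assembled with sample → individual →
   family fallback, size-filtered to 60–40,000 residues, deduplicated by
   sequence and doubled with reversed `DECOY_` entries.  An observed peptide
   confers MP support when it exactly matches a tryptic peptide of a variant
   protein spanning the substituted residue and is absent from the reference
   proteome digest.
4. **Quantification and statistics.**  Alt-carrying reads/spectra are summed
   per (genus, sample, layer ∈ {MG, MT, MG-only, MP}); conditions are
   compared with two-sided Mann–Whitney U tests.  Count matrices are
   collapsed to per-individual medians over visits, prevalence-filtered
   (≥ 20 reads, or ≥ 10 spectra, in 25% of individuals), and analysed with
   richness, Simpson's index of diversity `D = 1 − Σ pᵢ²`, Bray–Curtis
   dissimilarity `1 − 2·Σ min(uᵢ,vᵢ)/(Σuᵢ + Σvᵢ)`, and Spearman correlation
   screens with Benjamini–Hochberg adjustment (network threshold
   |ρ| ≥ 0.7, α = 0.001; plain screens α = 0.05).

## Worked example

```python
import straintrace as st

cfg = st.CohortConfig(
    n_families=2, individuals_per_family=4, visits_per_individual=3,
    taxa=[("Prevotella", 2, 2000, 1.5, 0.8),
          ("Streptococcus", 2, 2000, 1.5, 0.6),
          ("Bacteroides", 2, 2000, 0.4, 1.6)],
    variants_per_taxon=10, base_error_rate=0.001, seed=11,
)
truth = st.generate_cohort(cfg)                      # ground-truth ledger
result = st.run_transmission_analysis(truth)         # the full pipeline
print(result.summary.per_genus.to_string(index=False))
```

```
        genus   layer  n_variants  n_samples_with_variants  median_variants_per_sample  n_reads_or_spectra
  Bacteroides      MG           8                       24                         3.5                8680
  Bacteroides MG_only           2                       21                         1.0                2573
  Bacteroides      MP           4                       21                         2.0                 189
  ...
Streptococcus      MG           7                       21                         4.0                2564
Streptococcus MG_only           3                       15                         2.0                1099
Streptococcus      MP           5                       18                         2.0                  83
```

Each row counts the distinct transferred variants of a genus, the gut
samples in which they were seen, the median variants per such sample, and
their read (MG/MT) or spectral (MP) support.  Scoring against the truth
ledger and comparing conditions:

```python
print(st.evaluate_against_truth(result, truth))
# sensitivity: 1.0, false_positive_rate: 0.0, label_accuracy: 1.0, mp_support_rate: 1.0
print(result.comparisons[result.comparisons.layer == "MG_only"].to_string(index=False))
```

```
        genus   layer  n_t1dm  n_control    U  p_value  testable
  Bacteroides MG_only      12         12 91.5 0.272135      True
   Prevotella MG_only      12         12 27.0 0.010177      True
Streptococcus MG_only      12         12  0.0 0.000022      True
```

The generator's default transmission model gives *Streptococcus* a lower
mouth-to-gut transmission probability in T1DM individuals (0.2 vs 0.6); the
Mann–Whitney comparison of per-sample variant-read support recovers exactly
that contrast, while the equal-probability genera stay closer to the null.

A shell workflow is available through the `straintrace` CLI
(`simulate`, `call`, `track`, `protdb`, `match-peptides`, `stats`,
`report`); see `straintrace --help`.

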