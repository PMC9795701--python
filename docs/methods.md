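# Methods

This note documents the models, conventions and design choices behind
`straintrace`: what the pipeline assumes, what the synthetic cohort does and
does not emulate, and where numerical behaviour is deliberately pinned down.

## Variant calling model

Alignments are single-end, all-match records (CIGAR `<n>M`) on gut contigs;
records with indel operators are skipped and tallied.  Pileups count reads
per (position, base, strand).  When a position's coverage exceeds
`max_depth` (default 1000), reads are dropped deterministically: reads are
ordered by (start position, read id) and each position counts only the
first `max_depth` reads covering it.  A deterministic cap, rather than
random subsampling, keeps every run byte-reproducible.

The site quality is the Phred-scaled binomial tail
`QUAL = −10·log₁₀ P(X ≥ n_alt)`, `X ~ Binomial(n_ref + n_alt, e)`, capped at
255, with `e` the assumed per-base sequencing error rate.  This score makes
the conventional thresholds (`QUAL ≥ 20`, depth ≥ 10) meaningful and is
checkable against term-by-term tail sums.  `e` belongs to `CallParams`
(default 10⁻³); the end-to-end runner derives it from the reads' base
qualities, which the simulator emits as the constant Phred value
`min(40, −10·log₁₀ e)` — so on synthetic data the caller's error model is
exact.  When the simulated error rate is 0 the quality string saturates at
Q40 and the caller assumes `e = 10⁻⁴`.

Genotypes are haploid consensus calls: GT = 1 iff
`n_alt / (n_ref + n_alt) ≥ 0.5` (a tie counts as alternative — consensus
semantics on microbial contigs).  Only the majority non-reference base is
considered per site, ties broken alphabetically; the downstream criteria are
defined for a single alternative allele.  Whether a minimum-quality filter
should apply to QUAL or to a genotype quality is ambiguous in general
practice; QUAL is used here.

## Cross-site support criteria

For each variant called on a gut contig:

* criterion (i): alternative-allele depth > 0 on **both** strands in both
  the gut DNA and the oral DNA pileups.  "Positive allelic depth" is read as
  *alternative*-allele depth — the criterion exists to reinforce confidence
  in the alternative call, which total depth would not do.
* criterion (ii): haploid genotype 1 in the oral DNA, and in the gut RNA for
  the MG-MT class.

Oral DNA evidence is pooled across all of an individual's visits before the
criteria are evaluated.  A gut-RNA position with zero ref+alt coverage (or a
contig entirely absent from the RNA pileup) fails the RNA clause without
being an error: the variant falls through to MG-only.  A contig missing
from either DNA pileup is an error — it means the mapping inputs are
inconsistent.  Gut-DNA genotype is *not* required to be 1; the DNA clause of
the criteria names only strand depths, and requiring gut GT=1 would silently
drop minority transferred strains.

Taxonomic attribution of variant reads uses the contig→genus table rather
than per-read classification.  This is deterministic and dependency-free but
a fidelity gap versus per-read taxonomic classifiers: reads from a
mis-binned contig inherit the contig's label.

## Proteogenomics

Effects are annotated against non-overlapping CDS gene models with the
standard genetic code (bacterial table 11 differs only in start-codon
policy, which never affects a substitution's residue comparison).
Classification compares translated codons: identical → synonymous,
alternative codon a stop → nonsense, otherwise missense.  Variants outside
genes, ahead of the frame offset, or in an incomplete terminal codon are
"intergenic" (the last with a warning).  Each missense variant yields
exactly one variant protein with a single substituted residue;
multi-variant haplotype proteins are out of scope.

Database assembly follows the per-sample model with fallback: the sample's
own protein set, else the concatenation over the sample's individual, else
over the family; provenance records the level used.  Pool → size filter
(60–40,000 residues) → exact-sequence deduplication keeping the
lexicographically smallest identifier → reversed-sequence `DECOY_` entries.
Decoy construction is kept for structural faithfulness; no spectral search
or FDR estimation is performed here — observed peptides enter as a table
(sample, peptide, spectral count), standing downstream of an external
search engine.

In-silico digestion cleaves C-terminal of K/R except before proline
(deliberately *not* the Expasy rule with its additional WKP/MRP
exceptions), with up to 2 missed cleavages and peptide length 7–50 —
common search-engine settings.  A peptide confers MP support iff it equals
a tryptic peptide of a variant protein spanning the substituted residue and
does not occur in the reference proteome digest; peptides shared with the
reference are never counted, which makes support conservative but specific.

## Count-matrix statistics

Visits of an individual are not independent, so matrices are collapsed to
the per-individual median over available visits (mean of central values for
an even count) before any test.  The prevalence filter keeps features with
value ≥ 20 reads (≥ 10 spectra) in at least 25% of individuals.  Richness
counts features with positive abundance; Simpson's index of diversity is
`1 − Σ pᵢ²` on per-sample relative abundances; Bray–Curtis uses the
standard min-sum form; all-zero samples are flagged undefined rather than
silently imputed.

Mann–Whitney U uses the exact null distribution when both groups have ≤ 8
observations and the tie-corrected normal approximation otherwise; groups
smaller than 2 are flagged not testable.  Spearman screens use average
ranks, two-sided p-values, and Benjamini–Hochberg adjustment applied within
each analysis family (one network screen, one transfer-correlation battery)
— per-analysis thresholds make a per-analysis BH family the coherent
choice.  Constant features are excluded and reported, not scored.
Ordination (dbRDA/NMDS), hierarchical clustering and negative-binomial
differential abundance are interface points only: the module exports the
prepared matrices.

## Synthetic cohort generator

The generator emulates the structure that the pipeline's claims depend on,
and nothing more:

* **Cohort**: families with a fixed number of members, T1DM status assigned
  to alternating member slots (every family carries both conditions, as in
  a multiplex-family design), repeated visits; per individual-visit, four
  samples: oral MG, gut MG, gut MT, gut MP.
* **Genome**: random ACGT contigs per genus; each contig carries
  non-overlapping in-frame ORFs (ATG…TAA, alternating strands) placed at
  least one read length from the contig ends so planted sites sit in flat
  coverage.
* **Variants**: substitutions planted inside ORFs, at least one read length
  from gene ends (flat RNA coverage) and ≥ 153 bp apart within a gene so no
  ≤ 50-residue tryptic peptide can span two substitutions — every variant
  peptide then carries exactly one substituted residue, matching the
  one-protein-per-variant model.  Every individual carries every planted
  variant orally; transmission to the gut is drawn per (variant,
  individual) as Bernoulli(p(genus, condition)).  The default transmission
  map gives *Streptococcus* 0.2 (T1DM) vs 0.6 (control) with 0.5 for other
  genera — the cohort's central contrast.  Visits of an individual share
  the same carriage; only sampling noise differs (the analysis aggregates
  visits by median/pooling).
* **Reads**: uniform start positions, fixed read length (default 100 bp),
  strand Bernoulli(1/2), all-match; per-strand DNA coverage 30× and RNA
  coverage 20× by default (package choices typical of stool metagenomes).  Reads
  overlapping a variant present at that site carry the alternative base —
  strains are modelled as fixed haplotypes, so allele fractions are ~1, not
  intermediate.  Errors flip bases uniformly at the configured rate
  (default 10⁻³, Illumina-like); base qualities are the matching constant
  Phred score.
* **Expression**: each gene is expressed with probability 0.7 at a rate
  drawn Uniform(0.8, 1.5), else silent.  The lower bound keeps expressed
  genes comfortably above the RNA-genotype detection floor, so the
  MG-MT/MG-only split is decided by the expression flag and not by RNA
  sampling noise.
* **Peptides**: tryptic fragments (0 missed cleavages) of the expressed
  gut-strain proteins, sampled multinomially with weights ∝ expression ×
  genus gut abundance; total spectra per sample Poisson with mean
  `peptide_depth` (default 300).  Variant-spanning emissions are flagged in
  the truth ledger only when distinguishable from the reference digest.

Not emulated: paired/chimeric reads, indels, quality-score structure,
coverage biases, per-read taxonomic ambiguity, assembly errors,
spectrum-level mass simulation, protein inference and FDR.  Passing the
recovery tests therefore shows the pipeline's logic is correct under its
own assumptions — not that real-data noise modes (mapping artefacts,
strain mixtures with intermediate allele fractions, database
incompleteness) are handled.

Determinism: all streams derive from `(seed, stream-id, crc32(sample-id))`
seed sequences, so outputs are byte-identical for a fixed configuration and
independent of evaluation order.

## Validation problem sizes

The recovery analyses use a 2-family × 4-individual × 3-visit cohort with
3 genera × 2 × 2-kb contigs and 10 variants per genus (≈ 0.5 M simulated
reads per run); noise robustness repeats it over 10 seeds at 0.5% base
error; differential-transmission detection uses 15 individuals per
condition over 50 replicate cohorts at 10× coverage; correlation recovery
uses 6 genera × 30 samples over 50 replicates.  These sizes give the
detection problems comfortable but not degenerate margins and keep the
whole validation suite at desk scale.

## Known limitations

* One alternative allele per site; true multi-allelic sites lose the minor
  alternative.
* Cross-individual strain sharing, haplotype phasing and SNV-distance
  transmission scores are out of scope.
* The contig→genus table is trusted as-is; "unclassified" is the only
  fallback.
* MP support requires exact peptide string equality; modified peptides and
  I/L ambiguity are not modelled.
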