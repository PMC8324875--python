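# Methods

`paraloc` analyses a tandemly duplicated gene family on a single contig:
it calls gene losses from windowed read depth, annotates codon-level
consequences of SNVs (including premature stops that create polymorphic
pseudogenes), tests for adaptive protein evolution with
McDonald–Kreitman (MK) contrasts against orthologues and paralogues,
assigns amplicon sequencing reads to paralogues for expression
estimates, and evaluates paralogue-ratio-test (PRT) primer pairs in
silico. The motivating system is the mouse intelectin (*Itln*) locus:
six tandem copies of a 313-amino-acid lectin gene with ~90% mutual CDS
identity on a ~603 kb repeat-dense contig, with laboratory strains and
wild mice segregating large contiguous deletions and stop-codon alleles.

## Locus data model

A locus is one contig (A/C/G/T/N), a repeat-mask track, and a set of CDS
gene models. Internally all coordinates are 0-based half-open; the
on-disk gene table and VCF are 1-based and BED is 0-based, converted
only at the I/O boundary. Soft-masked FASTA letters are upcased on
input: the BED track is the single source of masking truth. Coordinate
transforms map contig positions through splicing and strand to CDS
offsets and 1-based codon numbers; both directions are exposed and are
exact inverses on every CDS base. Only SNVs flow through the analyses;
indel records are parsed and routed to an "unsupported" report, because
every downstream statistic here (consequence table, MK counts) is
codon-substitution based.

## Synthetic locus generator

The generator is the test bed for every stage and defines the simulated
study conditions:

- **Family structure.** One random ancestral open reading frame
  (default 942 bp = 313 codons + stop) is mutated independently per gene
  to reach a target expected pairwise identity (default 0.90), solving
  (1−p)² + p²/3 = I for the per-site substitution probability.
  Substitutions never create in-frame stops, and the start codon,
  terminal stop, and the two shared amplicon-primer sites are held
  fixed (the per-site rate is compensated so the overall identity still
  meets the target). Genes are placed on alternating strands — the real
  locus arose by recurrent inversion and duplication, so both
  orientations must be exercised — with 4 exons separated by 4 kb
  introns (~12.9 kb genomic span) and 75 kb intergenic spacers, each
  spacer carrying a central repeat-masked block covering 30% of its
  length. The defaults give a 602,652 bp contig, matching the scale of
  the 603,274 bp study contig.
- **Strains.** A strain is two haplotypes, each with a list of
  contiguous runs of deleted genes; each run is excised as one segment
  from (first gene start − 1 kb) to (last gene end + 1 kb), so
  breakpoints fall in intergenic repeat-like sequence as observed in the
  real strains. A haplotype may carry several separate runs (the
  CAST-like pattern loses genes 2 and 5 but keeps 3, 4 and 6; the
  SPRET-like pattern loses 2, 3 and 5 but keeps 4). True copy number is
  2 minus the number of deleting haplotypes, per gene. Codon-level
  variants (e.g. TGT→TGA stop gains) are injected at mapped contig
  positions with chosen zygosity, and a truth VCF records genotypes.
- **Reads.** Paired placements are drawn uniformly over the unmasked
  retained sequence of each haplotype (coverage is per haplotype), so
  masked repeats yield no reads — the mappability structure that makes
  raw depth non-uniform. The placement table records true reference
  intervals; FASTQ output with uniform substitution errors is available
  for external-aligner workflows. Indel errors are not modelled
  (SNV-only scope).
- **Amplicons.** Each gene's amplicon is its CDS between the two
  conserved primer sites (265 bp including primers). Reads are drawn
  multinomially from a specified mixture (down to 99.9%/0.1%), with
  optional per-base error; the realized source counts are stored as
  truth.

Everything is reproducible bit-for-bit under a fixed seed. The
generator does **not** emulate: realistic SINE/LINE repeat sequence
(masking is positional, not sequence-driven), mismapping between
paralogues, GC or insert-size coverage biases, indels, inversions, or
gene conversion. Passing recovery tests therefore demonstrates the
correctness of the counting, segmentation, and assignment logic under
the stated noise model — not robustness to alignment artefacts in real
data, which the variant filter's allele-balance rule and the
"not assessable in deleted strains" reporting partially address.

## Read-depth copy-number calling

Reads are counted into non-overlapping 5 kb windows by start position
(one window per read; the partial last window is kept). Counts are
normalised to the mean over informative windows — windows with masked
fraction > 0.9 are excluded from the mean and flagged; the mean over
informative windows is exactly 1 after normalisation, and the operation
is idempotent. Because depth along a repeat-dense contig is not uniform
but is reproducible across full-complement strains, copy state is read
from the **ratio** of the test profile to a designated full-complement
control profile; windows where the control's normalised depth falls
below 0.1 are uninformative. Homozygous deletions are segmented as
maximal runs of ≥ 2 consecutive informative windows with ratio < 0.25
(uninformative windows do not break a run). Per-gene copy state is the
median ratio over windows overlapping the gene span: < 0.25 → 0 copies,
< 0.75 → 1, otherwise 2; fewer than two informative windows →
ambiguous. The 0.25/0.75 thresholds are midpoints between the expected
diploid ratios {0, 0.5, 1}. A median above 1.5 is flagged as a putative
gain but not genotyped further. Note that normalising within the test
strain makes large deletions inflate the ratio elsewhere (a strain
retaining only one gene shows ratios well above 1 over retained
sequence); the copy-state thresholds are one-sided in the direction
that matters, so calls are unaffected. Breakpoint refinement below
window resolution is out of scope.

## Variant filtering and consequence annotation

Variants pass when site QUAL ≥ 30 and site depth ≥ 15 (the thresholds
applied to the study VCFs), and when every genotype's alternate-read
fraction is consistent with its class: heterozygotes within
[0.3, 0.7], homozygous-alt ≥ 0.9, homozygous-ref ≤ 0.1. The balance
rule makes an otherwise visual curation step explicit and reproducible;
the windows are configurable. Depth is interpreted as site DP.
Multi-allelic records are decomposed to biallelic SNVs before
annotation. Consequences are computed by rebuilding the reference codon
from the spliced CDS, substituting the alternate base (strand-aware),
and translating: synonymous, missense, stop_gain (with the truncated
peptide length — residues before the first in-frame stop), stop_loss,
or non_coding. Codons containing N translate to X. Allele frequencies
are reported per wild population as alt alleles over 2 × genotyped
diploids; inbred strains are listed as homozygous carriers without a
frequency; samples whose copy of the gene is deleted are reported as
not assessable and excluded from denominators.

## McDonald–Kreitman analysis

Per-sample diploid CDS haplotypes are rebuilt from the reference CDS
and genotyped SNVs (hom-alt on both haplotypes; het on one, alternating
deterministically in site order — MK counting is per-column and
phase-free under the two-most-frequent-codon rule, so the pairing
cannot change the table; this is asserted by test). Polymorphism pools
all focal haplotypes across strains and populations, singletons
included.

Codon columns containing a stop or non-ACGT base in any sequence are
dropped. Per retained column: more than one focal codon → polymorphic,
counted between the two most frequent focal codons (ties broken by
count then lexicographically); monomorphic and different from the
comparator → fixed. A column that is both polymorphic and divergent
contributes polymorphism only — no divergence is counted from a
segregating column. A polymorphic comparator is collapsed to its
per-column majority consensus.

Differences are counted by Nei–Gojobori pathway averaging: all
orderings of the differing positions are enumerated, pathways passing
through a stop codon are excluded (if all are blocked, all are kept),
and synonymous/nonsynonymous step counts are averaged, so the two
components always sum to the nucleotide Hamming distance. Fractional
pathway-averaged counts are rounded half-up immediately before the
exact test; the fractional table is also reported.

Significance uses a two-sided Fisher exact test computed by exact
integer hypergeometric enumeration (the two-sided p is the sum of table
probabilities no more probable than the observed, with ties compared as
exact integers; degenerate margins give p = 1). The neutrality index
NI = (Pn/Ps)/(Dn/Ds) is reported, undefined when Ps = 0 or Dn = 0.
Across a focal-genes × comparators matrix (self-pairs excluded),
Benjamini–Hochberg FDR at q = 0.10 is applied to all p-values as one
family.

Calibration under the simulator's neutral model (314-codon ORF,
comparator at ~8% divergence, 20 haplotypes with 100 segregating
sites): the rejection rate at α = 0.05 stays below 0.05 over 500
replicates (Fisher is conservative), and when one of four focal genes
receives ~5× the neutral nonsynonymous divergence, that gene yields the
matrix's smallest p-value in well over 90% of 100 replicates.

## Amplicon paralogue assignment

Reads are quality-filtered (mean Phred ≥ 20, no N — the stand-in for an
unspecified base-calling filter; configurable), trimmed by exact primer
match at both ends (untrimmable reads go to unassigned), collapsed to
unique sequences, and assigned by comparison to the per-gene reference
amplicons: the unique best match within `max_mismatch` (default 0 —
identical-sequence assignment) wins; ties are ambiguous. Percentages
are of assigned reads only; ambiguous and unassigned are reported
separately. With exact matching, sequencing errors cost yield, not
accuracy: error-free mixtures are recovered exactly, and at 0.5%
per-base error the estimated major-gene proportion stays within half a
percentage point of truth.

## In-silico PRT evaluation

Primer/template matching is IUPAC-aware (a primer code matches any base
in its expansion). Each template (both strands) is scanned for the
forward primer and a downstream reverse-primer site within the maximum
product size (default 3000 bp); the reported product runs from the
forward primer's 5′ start to the reverse primer's 5′ start, inclusive.
A template amplifies when its best site pair has fewer than 5
mismatches on both primers — the design rule that non-amplified
paralogues must carry ≥ 5 mismatches. Mismatch position is ignored by
default; an optional 3′-terminal-mismatch veto is available but off, as
the specificity rule is count-based. The report warns when two
amplified products differ by less than a gel-resolution margin (20 bp)
and flags assays that amplify nothing.

## Residue conservation

Functional positions are given in the reference protein's 1-based
numbering and mapped to alignment columns by gap-aware cumulative
counting; a gap in a target at the mapped column is reported missing.
Cells are flagged identical-to-reference, and an overlay marks
positions where a missense allele segregates (a residue can be
conserved in the reference yet polymorphic in the population). The
alignment is an input; a pairwise global aligner (BLOSUM62, gap open
10 / extend 1, via Biopython's PairwiseAligner) is bundled so small
analyses run without external tools.

## Numerical and design choices

- Reads are counted by start position only — order-independent and
  matching "reads per window" semantics; no fractional overlap.
- The normalisation mean is taken over informative (mask-filtered)
  windows; with many masked windows this differs from a whole-contig
  mean and is the deliberate choice here.
- Fisher's test is computed with exact integer arithmetic rather than
  floating-point hypergeometric sums so that tie inclusion is exact;
  it matches an independent enumeration to < 1e-12 over all 2×2 tables
  with total ≤ 60, and scipy's implementation on random tables.
- Rounding of pathway-averaged counts is half-up, applied once, at the
  test boundary.
- Copy-state thresholds (0.25/0.75), the control floor (0.1), the mask
  threshold (0.9), and the segmentation minimum (2 windows) are all
  parameters with the stated defaults.
- Degenerate inputs: empty placement sets give all-zero profiles;
  placements beyond the contig are collected as errors, not fatal;
  all-masked profiles refuse to normalise; an all-ambiguous amplicon
  run reports undefined percentages rather than NaN arithmetic.

## Problem sizes used by the test suite

Recovery tests run 20 diploid strains on the full-scale (~603 kb,
six-gene) synthetic locus at 10× per-haplotype coverage with 5 kb
windows; MK calibration uses 500 neutral and 100 selection replicates
of a 314-codon gene with 20 haplotypes; the Fisher oracle sweeps all
~635,000 tables with total ≤ 60; amplicon tests use 10,000-read
mixtures at 99.9%/0.1%. The whole suite completes in under a minute on
one CPU.

## Known limitations

- Copy gains are flagged, not genotyped; no split-read or
  discordant-pair breakpoint evidence is used.
- MK is unpolarised (no outgroup-based direction of fixation) and no
  α-style estimators beyond NI are provided.
- The two checks against deposited GenBank records (orthologue protein
  lengths; glycan-residue identity) require downloading the accessions
  with `scripts/fetch_accessions.py`; without network access their
  tests fail with a message naming the missing files.
- The simulator's noise model is substitution-only and mapping-free;
  see the generator section for what recovery results do and do not
  demonstrate.
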