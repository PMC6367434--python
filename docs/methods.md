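# Methods

## Model and scope

The package models a dual-site cytosine base-editing experiment in mouse
zygotes at the resolution of *diploid allele sequences*. Each founder is two
full-locus haplotypes; every analysis step (amplicon genotyping, zygosity,
phasing, cohort statistics) is derived from those sequences or from variant
tables, never from read-level data. Read alignment and variant calling
themselves (BWA, GATK HaplotypeCaller, LUMPY/SVTyper) are out of scope: the
off-target cascade consumes already-called variant records carrying the
standard annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum, SOR, DP, AD,
QUAL, GT).

## Target-site geometry

The toy reference is a single random chromosome (default 100 kb) with two
embedded targets whose protospacer starts are 9,000 bp apart:

* **Site C** — plus strand, NGA PAM (VQR-BE3 class). Protospacer positions
  3–11 spell the STAT5 motif `TTCNNNGAA`; the intended target C is
  protospacer position 5, with a second window C at position 7 available
  for bystander deamination.
* **Site E** — minus strand, NGG PAM (BE4 class). Protospacer positions 5–8
  are `TTCC`, whose plus-strand reverse complement is the ETS/ELF5 core
  `GGAA` (encoded as the degenerate pattern `GGAW`, i.e. GGA(A/T)); the
  target C is position 7, the bystander candidate position 8. A C→T edit on
  the protospacer strand appears as G→A on the plus strand and disrupts the
  motif.

The editing window defaults to protospacer positions 4–8 (1-based,
PAM-distal), the canonical BE3/BE4 window; it is configurable per site.
The Cas9 cut / nick locus is placed between protospacer positions 17 and 18.
Coordinates are 0-based half-open everywhere except at VCF boundaries.

## Founder simulation

Each allele draws one outcome per site: `intended` (all target C→T
conversions), `bystander` (a non-empty subset of non-target window Cs
converted), `indel` (85% deletions / 15% insertions, lengths 1–15 bp,
centered on the nick), or `WT`. Default per-allele intended rates (0.34 at
site C, 0.42 at site E) were chosen so that the *founder-level* probability
of carrying a mutation at each site (1 − (1 − p)²) approximates the
observed ~56% / ~66%; bystander (0.05) and small-indel (0.08) rates are
set to make those outcomes present but uncommon, as observed. Independent
per-allele draws cannot reproduce the positive correlation between sites
seen in real cohorts (47% doubly-mutated vs ~37% under independence) —
that correlation is a property of embryo-level editing efficiency that the
model does not attempt to capture; the packaged fixture, not the stochastic
generator, is the vehicle for the exact published counts.

When exactly one allele is edited at each site, the two edits land on the
same allele with probability `phase_bias` (default 0.6, matching the
observed 9/15 linked fraction). In `cas9` mode an allele additionally loses
the entire inter-site segment with probability `p_large_deletion`
(per-allele 0.41 ≈ founder-level 15/23); in `base_edit` mode this
probability must be zero — the generator enforces, and tests verify, that
no base-edited allele ever lacks the inter-site sequence.

All randomness derives from one top-level seed fanned out to fixed
per-component child streams (`default_rng([seed, stream_id])` with a
documented stream-id table), so equal seeds give byte-identical FASTA, VCF
and BED outputs.

## Genotyping

PCR is simulated by exact primer-sequence search: 20-mers at the two ends
of a 400–500 bp reference window centered on each protospacer. An allele
missing either primer sequence yields no product, which is exactly the
serial-PCR signature of a complete inter-site deletion; the call is
confirmed by a long-range product shortened by at least the inter-site
distance minus a ±50 bp tolerance. Present products are aligned globally
(match +2, mismatch −3, gap open −7 for the first gapped position, extend
−2) with Biopython's PairwiseAligner; ties are broken by taking the
aligner's first alignment and left-normalizing indels. The scores were
chosen so a single C→T is always a mismatch rather than a gap pair, and a
93 bp deletion stays one gap. A brute-force Gotoh dynamic program with the
same convention serves as the scoring oracle in the tests.

Classification precedence is total:
`large_deletion > indel > intended > bystander_only > WT`. A site counts as
*mutated* for the dual-site classification only when ≥1 allele is category
`intended`; zygosity is homozygous iff both alleles carry the full intended
edit set. Founders whose two alleles carry different non-WT categories are
reported `mixed` at that site and count as mutated when one of the alleles
is intended.

## Homozygosity denominator

Per-site homozygosity percentages are denominated over the founders mutated
at that site (5/18 → 28% at site C, 5/21 → 24% at site E in the fixture).
This is the only denominator under which both published percentages are
simultaneously reproducible from integer counts of a 32-founder cohort
(no integer x gives round(100·x/32) = 24); the all-founder fractions are
emitted alongside for audit and the choice is a keyword argument.

## Linkage

With ≈9 kb between sites (≪0.01 cM) recombination is treated as zero — an
assumption constant, not a hard-coded impossibility. Under it, the
offspring pattern sets of cis and trans double-het founders are disjoint,
so phasing from a founder × WT cross is exact given ≥1 informative
offspring; the default minimum of 4 offspring guards against the *null*
scenario of independently segregating edits, whose probability of
mimicking a perfect pattern is (1/2)^(n−1) ≤ 12.5% at n = 4 (verified by
Monte Carlo against the closed form). Homozygous founders are
uninformative: every offspring inherits the edit.

## Off-target cascade

Stage order per channel (configurable; defaults follow the filtering
pipeline's listing order):

* SNPs: hard filter → region masks → genotype/depth → AF + QUAL →
  indel proximity (±5 bp, inclusive borders, against surviving indels of
  both indel channels);
* simple indels: hard filter → region masks → genotype/depth →
  overlap-with-complex removal;
* complex indels: genotype → QUAL ≥ 100 → excess depth → region masks;

then per-channel control-population subtraction (a variant identical by
chrom/pos/ref/alt in *any* control sample is removed — subtraction is
placed last, a configurable choice), then intersection of the union of
survivors with predicted off-target site spans.

Numeric semantics: removal conditions are strict inequalities, so
keep-side boundaries are inclusive (DP = 10, AF = 0.10, QUAL = 130/100
kept); the excess-depth ceiling d + 3√d is compared as a real number with
no rounding; AF is computed from AD as alt/(ref+alt); missing annotations
never fire a hard-filter clause (GATK behavior; a strict mode removes them
instead); simple indels carry no quality gate by default since the stated
thresholds cover SNPs and complex indels only. Every stage is monotone and
idempotent and the report's per-stage counts telescope, which the tests
assert.

Off-target site enumeration is an exhaustive both-strand scan for
PAM-adjacent 20-mers within Hamming distance ≤ 4 of the guide; bulged
(gapped) matches are not modeled, a known divergence from prediction tools
such as CRISPOR. The scan is vectorized with a sliding-window comparison
and checked against a naive per-position oracle.

## Synthetic WGS cohorts

Variant sets emulate a 60× WGS cohort of 30 controls and 2 edited founders
on the toy genome: shared population variants written to every sample,
per-sample private variants, and optional spiked C→T edits at predicted
off-target sites in edited samples only. Annotation values come from
pass/fail mixtures per gate (default 15% of records draw exactly one
failing gate) so each record carries an `expect_pass` truth label; passing
depths are truncated into [10, ⌊d + 3√d⌋] so truth labels are exact.
Variant *counts* are scaled to the toy genome (≈100–200 records per
sample, ≤1,000 per cohort) — the generator reproduces the filtering
semantics, not genome-scale variant densities; sequencing noise, mosaicism
and multi-allelic records are not modeled, so passing tests demonstrate
correctness of the cascade logic, not performance on real call sets.

## Packaged fixture

`linkededit.fixtures` is a synthetic reconstruction of the 32-founder
reference cohort (the original per-founder alleles exist only in figure
form): per-allele outcome labels constrained by every published total — 3
C-only / 6 E-only / 15 both / 8 none; homozygotes 166, 169, 175, 186 at
both sites, F883 at C, one E-only founder; 9 of 15 co-targeted founders in
cis (the six trans founders het/het with edits on opposite alleles); five
site-E deletions of 2, 4, 6, 9, 11 bp and one 93 bp site-C deletion.
Fixture alleles are rebuilt deterministically on any reference, so the
summary statistics flow through the full alignment-based genotyper rather
than being read from a table.

## Numerical and degenerate-input choices

Percentages are rounded half-up to whole percent (raw fractions are also
emitted); empty cohorts raise for summaries and return empty profiles for
indel profiling; an observed amplicon shorter than 30% of its reference
window is flagged unalignable rather than aligned; interval tracks reject
empty/inverted intervals; track placement avoids all annotated features so
assay loci are never masked.

## Known limitations

* Diploid two-allele founders only; no mosaicism or >2 haplotypes.
* No read-level simulation; Sanger chromatogram artifacts are not modeled.
* Off-target scan ignores DNA/RNA bulges.
* The stochastic generator cannot reproduce between-site correlation of
  editing success (see above).
* The fixture is a constrained reconstruction, not transcribed alleles;
  per-founder details beyond the published totals are invented.
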