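# Methods

`sdrkit` implements the desk-scale analysis chain for mapping a
sex-determination region (SDR) from a sexed, resequenced diploid cohort and
characterising its divergence and degeneration. This note records the models
and procedures, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was open.

## The association scan

### Model

Each biallelic SNP is tested for association with sex on the 2×2 table of
allele counts by sex (genotype codes contribute 0 → two reference alleles,
1 → one of each, 2 → two alternates; missing genotypes contribute nothing).
The test is the two-sided Fisher exact test — the allelic association test —
using the standard "sum of small p" rule: the p-value sums the probabilities
of all tables with the observed margins whose hypergeometric probability does
not exceed the observed table's. Family-wise error is controlled at
`alpha = 0.05` by Bonferroni over the number of sites *tested* (after
filtering), not the number surviving. Sites with a degenerate margin (for
example, every individual of one sex uncalled) carry no allelic information
and report p = 1.

The Fisher test was chosen over a genotypic or trend test because, for a
fully sex-linked diagnostic site, the allelic table is maximally informative,
and the test is exactly checkable against a rational-arithmetic
hypergeometric enumeration (the suite verifies agreement to 1e-12 on every
table with margins ≤ 12).

### Variant filters

Four filters are applied before testing, in this order: site quality < 30;
more than two alleles; position within 5 bp of a supplied indel; cohort mean
depth below 1/3 or above 3× the genome-wide mean. Depth enters through a
windowed depth table (reads per bp per individual). One deliberate choice:
the per-site cohort mean is taken over individuals *with nonzero window
coverage*. Hemizygous Y-limited sequence is covered by carriers only; the
non-carrying sex contributes structural zeros that say "absent", not
"low-quality", and averaging them in would silently discard exactly the
hemizygous sites the scan is meant to find.

### Heterogamety, recombinants, intervals

Pooled over significant sites, the heterogametic sex should be mostly
heterozygous and the homogametic sex mostly homozygous. The call is XY when
male heterozygosity ≥ `het_high` (0.6) and female ≤ `het_low` (0.2), ZW for
the mirror image, otherwise UNDETERMINED. The thresholds sit well apart from
the empirical patterns this scan targets (male het in the 70–95% range,
female het below ~10% once recombinants are removed) and are configurable.

Rare X–Y recombination gives a homogametic individual the heterogametic
genotype pattern across the SDR. Any homogametic individual whose personal
heterozygosity across significant sites exceeds
`recombinant_het_threshold = 0.5` is flagged and excluded, and the profile is
recomputed. Exclusion can only reduce the homogametic pooled heterozygosity
(a property the suite asserts).

Significant sites are delineated into intervals by gap-joining (join gaps
≤ 1 Mb, require ≥ 5 sites). Before joining, sites are split into two classes
by their own evidence: *hemizygous-type* (homogametic-sex missingness >
`missing_high` = 0.5) versus *SDR-type*. The two classes are clustered
separately; without the split, a hemizygous Y-limited segment embedded
inside the SDR would be absorbed into the surrounding diploid-SDR cluster
and could not receive its own label. Intervals are then labelled:

- **X_SDR** (Z_SDR under ZW): heterogametic-sex heterozygosity ≥ `het_high`,
  homogametic ≤ `het_low`, homogametic normalized depth within 2×0.15
  of diploid (1.0);
- **Y_SPECIFIC** (W_SPECIFIC): homogametic missingness > 0.5, heterogametic
  normalized depth within ±0.15 of the hemizygous expectation 0.5, and
  homogametic normalized depth ≤ 0.1;
- **NOT_SEX_LINKED** otherwise.

Normalized depth is per window and sex: the mean over individuals of
(window depth / that individual's genome-wide mean), so a diploid window
sits at 1.0 regardless of per-individual coverage differences.

## Y-read identification

Two routes, merged with provenance, mirror how Y-limited sequence is
recovered without a Y reference:

1. **Sex-specific k-mers.** Canonical 30-mers (lexicographic minimum of a
   k-mer and its reverse complement) are catalogued per individual; a k-mer
   is male-specific when present in ≥ 20 males and absent from every female
   (`max_females = 0` is strict absence). A read is binned if it carries at
   least one such k-mer. For error-free reads lying fully inside Y-limited
   sequence with read length ≥ k, recall is exactly 1 by construction.
2. **Read-backed phasing.** Heterozygous sites connected by at least one
   read form a block (union-find over per-read site sets). Reads are
   two-coloured greedily in order of leftmost covered site: each read joins
   the haplotype consensus it agrees with best and is dropped (and reported)
   if it disagrees with both beyond a one-site mismatch tolerance. The block
   haplotype carrying the male-associated allele at the majority of
   sex-associated sites is labelled Y; ties are ambiguous and excluded. The
   greedy colouring replaces a weighted minimum-error-correction solver; on
   error-free instances with ≤ 10 sites the suite certifies it against an
   exhaustive optimal complementary two-colouring.

## Divergence

### Gametolog Ka/Ks (Nei–Gojobori 1986)

Codon pairs come from a codon-aware alignment (translated proteins aligned
under BLOSUM62, codons threaded back, gap codons dropped). Per codon, each
position contributes fractional synonymous/nonsynonymous site counts: of its
three possible substitutions, those creating stops count as neither, the
rest split by whether the encoded amino acid changes, each worth 1/3 site.
Site counts are averaged over the two sequences. Differences are averaged
over all orderings of single-base steps between the two codons, skipping
paths that pass through a stop codon (if every path does, stop-passing steps
are counted as nonsynonymous rather than discarding the codon). Proportions
pS = Sd/S and pN = Nd/N are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is flagged saturated. This NG86 estimator
stands in for a maximum-likelihood codon model; at the divergence scale of
young sex chromosomes (Ks ≲ 0.2) the two agree closely, and NG86 is exactly
verifiable against pathway enumeration, which the suite does for all codon
pairs with ≤ 2 differences.

### Strata test

Evolutionary strata would appear as a step in Ks along the X position. The
statistic is the maximum, over breakpoints leaving ≥ 4 points per side, of
the absolute difference in mean Ks between left and right segments; its null
distribution comes from permuting Ks over positions (seeded; p-value
(hits+1)/(n_perm+1)). A breakpoint is reported only at p < 0.05. This is an
explicit operationalisation of a qualitative judgement; the permutation p is
checked against exhaustive enumeration on 8-point instances.

### LTR insertion dating

An LTR retrotransposon's two arms are identical on insertion and diverge
neutrally afterwards. Arm divergence is corrected for saturation with
Kimura's two-parameter distance, K = −½·ln(1−2P−Q) − ¼·ln(1−2Q), with P and
Q the transition and transversion difference proportions (non-ACGT sites
excluded; non-positive logarithm arguments flag saturation). Insertion age
is K/(2μ) with μ = 2.5×10⁻⁹ substitutions per site per year, the rate
conventionally used for these genomes. Round-trip accuracy is within 10% of
truth for ages 1–20 Myr at 5 kb arms.

### Gene classification

Genes on the X- and Y-SDR haplotypes are labelled by reciprocal-best-hit
(RBH) logic over global alignment scores (score thresholds stand in for
E-values, which are undefined without database statistics at this scale):
X_Y_SHARED (RBH partner on the other haplotype), ANCESTRAL (hit in the
corresponding outgroup region), AUTOSOMAL_TRANSPOSITION (no outgroup-region
hit but mutual best hit to an autosomal gene), LOST (no X–Y homolog, but a
pseudogene relic and/or ancestral homolog exists; the loss is recorded
against the haplotype carrying only the relic), SPECIFIC (none of the
above). Labels may combine, except LOST/SPECIFIC. Tandem duplicates are
pairs above the score threshold starting within 500 kb on one haplotype.
Pseudogenes require > 70% alignment identity to an intact parent gene,
≥ 50% coverage (the coverage cut is this package's declared default) and at
least one reading-frame disruption — a premature stop in the threaded parent
frame or an indel run whose length is not a multiple of 3. Pseudogene
alignment penalises gaps more than mismatches (−2 vs −1); with equal costs
the aligner hides substitutions inside gaps and inflates per-column identity
above threshold for copies that are far more diverged than 30%.

## Mutation load

Coding SNVs are classified straight from the standard genetic code: SYN
(amino acid unchanged), LOF (stop gained, stop lost, or loss of the
initiator ATG), MISSENSE otherwise; minus-strand genes are handled by
reverse complement, and the annotation is verified against brute force over
all 576 single-nucleotide codon changes. Missense variants are split
DEL/TOL by a conservation-based consensus of two scorers over per-gene
ortholog alignment columns: scorer A votes deleterious when the reference
residue's column conservation ≥ 0.8 and the variant residue is absent from
the column; scorer B when the variant residue's column frequency < 0.05.
DEL requires both votes. This two-rule stand-in replaces externally trained
predictors while preserving the consensus structure (a variant is
deleterious only when both methods agree); its thresholds (0.8, 0.05) are
declared defaults, not fitted values.

Load is compared between regions on per-gene DEL/SYN and TOL/SYN ratios
(LOF pooled with DEL by default; SYN is the neutral denominator, genes with
zero SYN have undefined ratios and are dropped; regions with fewer than five
usable genes are flagged and excluded). Each region pair gets a two-sided
Mann–Whitney U test plus a seeded label-permutation test on the difference
of mean ratios; Holm correction is applied across pairs per metric. Under
the null the rank-sum test's realised type-I error is ≤ 6% at nominal 5%
(mildly liberal-to-conservative depending on ties), and power for a planted
2× DEL/SYN enrichment at 50 genes per region exceeds 80%; both are measured
by the acceptance script.

## The synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
under which everything above is validated.

**Cohort.** 30 males and 30 females (the motivating resequencing designs
used 30/30 and 26/30) genotyped at ~32× mean coverage on a two-chromosome
genome (12 Mb carrying the SDR at 6.39–8.73 Mb with a hemizygous Y-specific
segment at 7.40–7.90 Mb, plus a 6 Mb autosome). SNP density is 5×10⁻⁵ per
bp — a declared default, since the real cohorts' density is not published;
it yields a few hundred autosomal sites and ~100 SDR-diagnostic sites, ample
for the interval statistics. Autosomal sites segregate under Hardy–Weinberg
with allele frequency uniform on [0.05, 0.5], independent of sex, with 2%
missingness. SDR-diagnostic sites are heterozygous in the heterogametic sex
and homozygous in the homogametic sex (mirrored under ZW), with a 2%
genotype-error rate. A homogametic individual is a recombinant with
probability 0.1 (3 of 30 in the motivating data) and then carries the full
opposite-pattern haplotype — whole-haplotype swaps, matching the observed
all-or-most heterozygosity of real recombinants — including the hemizygous
segment.

**Hemizygous segment.** Carriers are called homozygous-alternate at 90% of
sites; the non-carrying sex is uncalled at 75% of sites, with the remainder
called homozygous-reference. The residual call rate emulates reference
misalignment — in the motivating data 73.36% of female genotypes were
missing on the Y contigs, not 100% — and it is what makes these sites
testable at all: with total missingness the allelic table is degenerate and
no site in the segment could reach significance. Carrier depth in the
segment has expectation half the genome-wide mean; non-carrier depth is
zero.

**Depth.** Window means (100 kb windows) are drawn from a negative binomial
with mean m and variance m + 0.1·m² (dispersion 0.1 adds realistic
overdispersion; the real cohorts publish only ~32×/~38× means). Setting
dispersion 0 recovers Poisson.

**Sequences.** Gametolog pairs are built from codon families whose third
position is fully synonymous and whose first two positions are fully
nonsynonymous under the standard code (GTx, GCx, ACx, CCx, TCx, GGx, plus
the ATG start), so the NG86 synonymous site count is exactly one per
non-start codon and the planted Ks calibrates analytically: third positions
flip to another base with probability p = (3/4)(1 − e^(−4·Ks/3)). LTR arms
descend from one ancestral arm, each lineage evolving under a two-class
(Kimura) substitution process with transition/transversion rate ratio
κ = 2.0 for `age` years at rate μ, giving total divergence expectation
2μ·age. Reads are error-free with uniform starts and truth-tracking ids.

**What the generator does not emulate — and what passing therefore does not
show.** No sequencing error, indels, structural variants, GC or mappability
bias in depth, linkage disequilibrium outside the SDR, population structure
or relatedness, partial (as opposed to whole-haplotype) recombinants, or
reference bias beyond the fixed hemizygous call model. Recovery rates
measured here are therefore upper bounds on real-data performance; the
oracle checks (Fisher, NG86, K2P, phasing), by contrast, are exact
statements about the implementations themselves.

## Reproducibility and numerical choices

Every stochastic routine takes an explicit seed and touches no global state;
identical arguments give byte-identical outputs (asserted end-to-end through
the CLI). Intervals are 0-based half-open internally; VCF and GFF3 remain
1-based on disk; BED output is 0-based. Phased genotype separators are
accepted and treated as unphased. Fisher ties follow the standard
sum-of-small-p rule. Alignment tie-breaking is delegated to a deterministic
dynamic-programming traceback. Percentages in reports are rounded to two
decimals at presentation only. Problem sizes in the test and acceptance
runs (25–50 replicate cohorts, 100–200 replicate sequence fixtures, 500–1000
calibration simulations) were chosen so that Monte-Carlo error is small
against each check's tolerance.

## Known limitations

- With unusually many recombinants in a draw (e.g. 9 of 30 homogametic
  individuals, ~2% probability at the default rate), allele counts at
  SDR-diagnostic sites lose Bonferroni significance and the heterogamety
  call degrades to UNDETERMINED rather than guessing; recombinant detection
  also weakens because it conditions on significant sites.
- The QV→accuracy conversion follows the Phred definition exactly; one
  published value (QV 35.23 printed as 99.96%) appears truncated rather
  than rounded and is reproduced as 99.97% by the formula.
- RBH over global alignment scores assumes comparable sequence lengths;
  highly fragmented gene sets would need local alignment, which is out of
  scope at desk scale.
- The conservation-based DEL/TOL stand-in is not a trained predictor;
  its calls are internally consistent (consensus rule, SYN never scored)
  but not calibrated against experimental deleteriousness.
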