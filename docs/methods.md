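# Methods

This note records the models, estimators and numerical choices behind
`sexscan`, and what the synthetic-data generators do and do not emulate.

## Coordinate conventions

Files (VCF, sync, printed tables) are 1-based inclusive; all internal
interval arithmetic is 0-based half-open, converted in one audited module
(`sexscan.coords`).  Structural-variant records keep the DELLY-style printed
convention in which `length = end − start`.

## Family scan

**Fisher's exact test.**  Per site, the 2×2 table counts ref/alt alleles in
male vs female offspring; parents are excluded so their genotypes cannot
bias the table.  The two-sided p-value follows the *method of small
p-values*: the sum of hypergeometric probabilities, over all tables with the
observed margins, no larger than the observed table's.  Ties are resolved
exactly — probabilities are compared as integer numerators over the common
denominator C(n, c₁), with a float produced only at the final division.
Note that for unequal margins the two one-sided extremes are *not*
symmetric: a fixed difference between 15 males and 14 females has p equal
to 1/C(58,30), not 2/C(58,30), because the opposite extreme table is far
likelier than the observed one.  Monomorphic sites report p = 1 and an
undefined (NaN) F_ST.

**F_ST.**  Weir & Cockerham's (1984) θ for two groups, computed from the
per-group sample sizes, allele frequencies and observed heterozygosities.
θ is invariant under allele relabelling and group exchange, reaches 1 at a
fixed difference, and is reported as NaN when all variance components
vanish.  Other AMOVA-style estimators (e.g. the one embedded in RAD-calling
pipelines) may differ numerically at small samples.

**Inheritance classification.**  Candidate sites are those significant at
α (default 0.01) with both parents called.  XY-informative sites have a
heterozygous sire and homozygous dam; each offspring call is labelled
`maternal` (matches the dam), `paternal` (matches the sire),
`paternal-specific` (homozygous for the allele the dam lacks — the YY-like
pattern), `neither`, or `missing`.  Matching uses unordered genotype
equality; half-missing calls count as missing.  Per-site concordance is the
fraction of sons labelled paternal plus daughters labelled maternal among
the site's non-missing calls; ZW mirrors the computation through the dam.

The *decision statistic* is the peak per-site concordance.  An aggregate
over all informative sites is also reported but deliberately not used for
the decision: sites linked to, but megabases away from, the SD locus stay
statistically significant while accumulating recombinant offspring and
polarity-inverted configurations (the sex-specific allele matching the
homozygous parent), so the aggregate saturates near 0.6–0.7 even in a
perfect XY family.  The peak statistic reaches 1.0 exactly at SD-flanking
sites in error-free families, and the competing model's peak stays near 0.5
(or is undefined when no informative significant site exists, the typical
outcome for the wrong heterogamety).  The declaration threshold is 0.9,
exposed as a parameter.  Per-offspring label switches between consecutive
informative sites are reported as candidate recombination-breakpoint
intervals.

**Sex-ratio test.**  1-df χ² against 1:1 without continuity correction:
49:51 gives χ² = 0.04 (p ≈ 0.84), 55:45 gives χ² = 1.0 (p ≈ 0.32).

## Pool scan

Per-site pooled F_ST uses nucleotide diversity with the read-count
correction π = n/(n−1)·(1 − (a/n)² − (b/n)²); π_S is the unweighted mean of
the two pool π values and π_T is computed from the summed counts, with
F_ST = (π_T − π_S)/π_T reported as 0 when π_T = 0 and clamped to [0, 1].
Pool-size-specific corrections used by some pooled-sequencing tools are not
applied; at depths below ~10 reads the values may differ from those tools.

The Sex-SNP-Finder criterion is implemented *major-allele based*
(reference-free): for the XY pattern a site is flagged when both pool
depths lie in [10, 100], the male-pool minor allele is backed by ≥ 2 reads,
the female pool's major-allele frequency is ≥ 0.9, and the frequency in the
male pool of the female pool's *minor* allele lies in [0.3, 0.7].  The
reference-free choice matters because the Y-specific allele need not be the
VCF alt allele.  Windows are non-overlapping 10 kb bins anchored at
position 0 of each chromosome.

## B blocks

Amplified fragments of ordinary chromosomes carried on supernumerary
B chromosomes pile up on the reference as localized blocks of very high,
highly polymorphic coverage; in a pool that carries Bs they mimic the
sex-patterned signature and the resulting noise can mask the genuine
sex-determinant signal.  Blocks are called per pool as runs of bins with
depth > 10× the pool's genome mean; the mean is computed after discarding
the top 1% of bins so the artefact does not inflate its own baseline, and
merged runs shorter than 1 kb (a choice; the detection is not sensitive to
it at desk scale) are dropped.  A block footprint present in the same-sex
pool of every population is reported as a "sex-linked candidate"; anything
else — e.g. blocks in one population's female pool and the other's male
pool — is a "sex-independent artefact".  Masking removes the sites inside
any flagged block from the pooled scan.

## Depth-based structural model

The duplication/deletion caller works in read-depth space only (no
paired-end or split-read evidence): the male/female per-bin depth ratio is
segmented into piecewise-constant pieces and the segments are interpreted
under the CN3/CN2 model — a diploid male carrying one extra Y copy of a
span shows ratio 1.5 inside it, reverting to 1.0 where one of the two
Y copies is deleted.

Numerically: the *log* ratio is segmented (the variance-stabilizing scale
for Poisson depths), with the flat female profile first smoothed by a
51-bin moving average — the reference baseline carries no breakpoint
signal, so smoothing removes its sampling noise from the ratio without
blurring change-points.  Segmentation is greedy least-squares binary
segmentation with a BIC-style stopping penalty 2σ̂²·log n (σ̂ from the
median absolute successive difference, hence exactly 0 — and exact
recovery — on noiseless profiles), followed by merging of adjacent segments
within half a copy-level separation and a boundary-polish pass that
re-estimates every change-point between its fixed neighbours.  Segment
means within ±0.15 of 1.5 are duplication-level; segments back near 1.0
nested between them are deletions of one Y copy.  Each breakpoint's
confidence interval is one bin.  On the packaged duplication geometry with
Poisson noise at 40× and 50 bp bins, the mean absolute breakpoint error is
~28 bp (about half of it bin-quantization of off-grid true breakpoints).

**Y-haplotype model.**  The Y region is the reference region with the
duplicated span present twice in tandem; the junction between the two
copies concatenates the truncated 3′-gene fragment of copy 1 with the
truncated 5′-gene fragment of copy 2 (the internal chimera).  Each internal
deletion removes one of the two copies of its span; under the default
`truncated-copy` placement a deletion is assigned to the copy in which its
flanking gene fragment is truncated (the parsimonious scenario, since the
deleted piece was already non-functional), with `intact-copy` selectable as
the alternative.  The total length, (region) + (dup) − Σ(deletions), is
placement-invariant, and segments always tile it exactly.

**Annotation.**  Gene models carry strand, exons, phased CDS and UTRs;
feature numbering follows transcription order, so genes antisense on the
reference are numbered from the genomic right.  For a coding SNP the
spliced CDS is rebuilt from the reference segment (reverse-complementing
for antisense genes), the codon located through the first segment's phase,
and the amino-acid change reported in three-letter form (synonymous
changes report none).

**Marker rule.**  The three *amh* PCR markers map to genotypes with YY
evaluated before XY so the X-negative supermale pattern is never read as
XY: amhX⁻ with both Y markers → YY; amhX⁺ with either Y-copy marker → XY;
amhX⁺ with both Y markers absent → XX; amhX⁺ with the truncated-copy marker
absent and amhY undetermined → ND; a pattern with no marker present is
rejected.

## Synthetic data

**Families.**  Four founder haplotypes (two per parent) are drawn
independently at uniform allele frequencies, except inside a diverged
block of ±1 Mb around the SD position where the three homogametic-lineage
haplotypes carry the reference allele and only the Y (or W) carries the
alternate — the configuration that makes a site sex-patterned at all.
Without this block, half of the sire-het/dam-hom sites would have the
Y carrying the dam's allele, inverting the offspring labels.  Gametes are
recombinant mosaics under a Haldane (no-interference) model: a Poisson
number of crossovers at `recomb_rate × chrom_length` (default 0.03/Mb ×
40 Mb ≈ 1.2 per meiosis), uniform positions.  Offspring sex is fixed by
conditioning the transmitting parent's gamete on the SD-site haplotype.
Genotyping error is a symmetric per-allele flip (default 0.5%),
missingness drops whole calls (default 10%), both independent per call.
Defaults mirror the sequenced F1 families: 15 sons + 14 daughters plus parents.

**Pools.**  Read counts are binomial draws from the design pool frequency
at a Poisson per-site depth (defaults 20×; the sequenced pools ranged
16–39×), so ref + alt equals depth by construction.  Sex-patterned sites
(default 5% of sites — the simulated segment represents the SD-region
context, not a genome-wide average) put the homogametic pool at
near-fixation limited only by a 0.5% sequencing-error rate, and the
heterogametic pool at 0.5, the physical model of an X/Y divergent site.
B-block sites (default 1%) occupy contiguous runs, multiply depth by the
block fold (default 15×) in exactly one pool and sit at intermediate
frequency there, mimicking the XY signature.  Composition sampling within
the finite pool of fish is *not* modelled; with it, neutral sites drift
enough that the single-site false-flag rate rises to ~1%, which is worth
remembering when transferring single-site results to real pools — the
windowed counts, not single flags, are the robust output there.

**Depth profiles.**  The female profile is flat at the design depth; the
male profile follows the CN3/CN2 expectations with length-weighted values
in bins partially overlapping a boundary, plus optional Poisson noise.
Defaults reproduce the packaged Koka duplication geometry (21,512 bp
duplication, two internal deletions) at 40× with 50 bp bins.

What passing tests on these generators shows: the estimators recover
*planted* signal of the stated strength under binomial/Poisson sampling
noise.  What they do not show: robustness to mapping artefacts, allele-
specific bias, indel-realignment noise, pool-composition drift, or
reference errors — none of which the generators emulate.

## Known limitations

* The depth-only SV caller cannot see copy-neutral rearrangements, cannot
  resolve which *amh* copy carries a given small variant (short reads
  cannot either), and reports breakpoints at bin resolution.
* The pooled F_ST estimator is the simple π-based form; cross-tool
  numerical agreement at very low depth is not guaranteed.
* The family classifier assumes a single two-parent family per run.
* Whether the duplicated block inserted upstream (within *oaz1*) or
  downstream (within *dot1l*) is not decidable from depth evidence; both
  placements are representable and neither is asserted.
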