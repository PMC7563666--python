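# sexscan

Genome scans and structural reconstruction for a fish sex-determining
region, built around the LG23 *amh* locus of wild Nile tilapia
(*Oreochromis niloticus*).

Wild tilapia populations determine sex with a male-heterogametic (XX/XY)
system whose master locus is a Y-specific tandem duplication spanning the
anti-Müllerian-hormone gene *amh*.  Two complementary sequencing designs can
localise it without a Y assembly: ddRAD-genotyped F1 families (parents plus
sexed offspring) and whole-genome sequencing of phenotypic-sex pools.  This
package provides the full desk-side analysis stack for both designs:

* **Family scan** (`sexscan.family_scan`) — per-site two-sided Fisher's
  exact test on the offspring allele-count table (exact "method of small
  p-values" convention) and Weir–Cockerham θ between male and female
  offspring; inheritance-pattern classification (XY vs ZW) from parentally
  informative sites with per-offspring recombination-breakpoint intervals;
  1-df χ² sex-ratio test.
* **Pool scan** (`sexscan.pool_scan`) — pooled F_ST per site,
  F_ST = (π_T − π_S)/π_T with π = n/(n−1)·(1 − Σp²) from read counts;
  pooled Fisher tests; the Sex-SNP-Finder XY/ZW criterion (one pool fixed or
  nearly fixed, the other at intermediate frequency) with 10 kb windowed
  counts.
* **B-block handling** (`sexscan.bblock`) — detection of high-coverage
  blocks (>10× the robust genome mean) produced by supernumerary
  B chromosomes, a cross-pool sex-consistency verdict, and masking of the
  affected sites from the pool scan.
* **Structural model** (`sexscan.svmodel`) — duplication/deletion breakpoint
  estimation from male/female depth ratios by least-squares binary
  segmentation; breakpoint gene context against strand-aware gene models;
  reconstruction of the Y-haplotype segment model (tandem duplication with
  internal single-copy deletions) and its total length; small-variant
  annotation with codon-level amino-acid effects; marker-based XX/XY/YY
  genotype prediction from the three *amh* PCR markers.
* **Synthetic data** (`sexscan.simdata`) — seeded generators for families
  (Haldane recombination, genotyping error, missingness), sex pools
  (sex-patterned, neutral and B-block sites) and depth profiles (duplication
  with internal deletions, Poisson noise), so every stage is testable
  without any download.
* **I/O** (`sexscan.io_formats`) — VCFv4.2 (GT/DP), Popoolation2 sync,
  bedGraph, GFF3, FASTA segments, and packaged TSV fixtures of the wild-population
  marker, structural-variant and small-variant tables.

## Worked example

Reconstruct the Y haplotype of the Koka population from the packaged
structural-variant table:

```python
import sexscan as sx
from sexscan.svmodel import build_y_haplotype, sv_length

t3 = sx.read_table_fixture("table3")
dup  = next(r for r in t3 if r.population == "Koka" and r.type == "duplication")
dels = [r for r in t3 if r.population == "Koka" and r.type == "deletion"]
print(dup.start, dup.end, sv_length(dup))     # 34491225 34512737 21512

model = build_y_haplotype((dup.start - 10_000, dup.start + 32_000), dup, dels)
print(model.total_length)                      # 52253
for s in model.segments:
    print(s.label, s.deletions, s.length)
```

```
34491225 34512737 21512
52253
flank-5' [] 10000
dup-copy-1 [(34503117, 34509103)] 15526
dup-copy-2 [(34493315, 34498588)] 16239
flank-3' [] 10488
```

The 42 kb reference span gains the 21.5 kb duplicated block and loses the
two shared single-copy deletions (5,273 bp and 5,986 bp), giving a
~52 kb Y-specific region.  Under the default `truncated-copy` placement each
deletion is assigned to the copy whose flanking gene fragment is already
truncated by the duplication boundary: the *oaz1*-side deletion to copy 2
and the *dot1l*-side deletion to copy 1.

An end-to-end synthetic run — two populations, family scan, pool scan with
B-block masking, depth segmentation — is one command:

```sh
sexscan demo --seed 5 --out demo_out
```

which reports, per population, the selected inheritance model (`XY`), the
significant-site interval on the chromosome, the pooled flag counts before
masking, the B-block verdicts (`sex-independent artefact` when the blocks
sit in a female pool in one population and a male pool in the other) and
the recovered duplication/deletion breakpoints.

## Layout

```
src/sexscan/       library modules (records, simdata, io_formats, stats,
                   family_scan, pool_scan, bblock, svmodel, genes, cli)
src/sexscan/data/  packaged TSV fixtures of the printed tables
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    models, estimators, numerical choices, limitations
```
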