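# Methods

## Scope and model

`plastidseq` quantifies the post-transcriptional layer of chloroplast gene
expression from a strand-specific RNA-seq alignment: stranded coverage,
exon/intron relative abundance (RPKM), intron splicing efficiency, and
C-to-U editing efficiency.  It consumes an existing coordinate alignment
(single-end, splice-aware, SAM/BAM) against a genome that contains the
organellar sequence, plus GFF3 annotation of exons, introns/splice sites and
editing sites, and a genome FASTA.  It does not align reads, call novel
junctions, or discover editing sites: the annotation is authoritative.

All coordinates are 0-based half-open internally; every text output is
1-based inclusive, the GFF3 convention.

### Subgenome extraction and library statistics

Reads whose reference name equals the target subgenome (e.g. `ChrC`) are
extracted; `mappable_reads` counts all primary, non-QC-fail, non-supplementary
records in the input and `mapped_reads` those on the target.  The mapped
fraction is printed as `100 * mapped / mappable`, rounded half-up to one
decimal — the convention used in published alignment-rate tables (30.252%
prints as 30.3, where round-to-even would print 30.2).

Secondary records are kept in the extracted stream (a chloroplast aligner is
typically allowed two placements so the large inverted repeat receives
symmetric coverage) but each read is counted once, by its primary record, in
library statistics and in the RPKM denominator.

### Coverage and RPKM

Per-nucleotide depth is accumulated separately for the two transcript
strands.  The transcript strand of a record is derived from its alignment
strand under a configurable protocol (`strandness`): `forward` (default,
transcript strand = alignment strand), `reverse` (dUTP-style, flipped), or
`unstranded`, in which every read is assigned to the plus strand — a
documented limitation rather than a half-weighting scheme.  Only M/=/X/D
CIGAR operations contribute depth; N gaps (spliced-out introns) contribute
nothing.

Window coverage uses 100 nt windows stepping by 50 nt (both configurable),
starting at position 0 with the final windows truncated at the genome end;
each window's raw depth sum is normalized per million reads
(`raw_sum * 1e6 / total_reads`).

Feature abundance uses

```
RPKM = C * Ri / (Ti * L),    C = 1e9
```

where `Ri` is the number of read alignments whose aligned blocks overlap the
feature by >= 1 nt on the feature's strand, `L` the feature length, and `Ti`
the normalization total.  `Ti` defaults to the reads mapped to the target
subgenome (`ti_mode="subgenome"`), which makes chloroplast-to-chloroplast
comparisons insensitive to differences in nuclear contamination between
libraries; `ti_mode="library"` switches to whole-library mappable reads.
Because gap blocks create no overlap, a spliced read spanning an intron does
not count toward that intron's `Ri`.

### Splicing efficiency

For each intron with donor `d` (first intronic base) and acceptor `a` (first
exonic base after the intron), reads on the host gene's strand are classified
as:

* `jR` — the alignment contains an N gap exactly equal to `(d, a)`, with at
  least `min_overhang` aligned nt immediately on each side;
* `liR` — a contiguous aligned block covers `[d - min_overhang, d + min_overhang)`;
* `riR` — likewise at `a`.

```
SE = jR / (jR + (liR + riR) / 2)
```

The factor 1/2 reflects that an unspliced transcript presents two
exon/intron boundaries where a spliced one presents a single junction; with
uniform read starts over the molecule, the estimator is unbiased for the
spliced fraction.  A read that traverses the whole intron unspliced is
counted at both boundaries, which is what the averaged denominator expects;
counting it once would bias SE upward for introns shorter than the read
length.  `min_overhang` defaults to 1 nt, the most permissive reading of
"spanning"; exact junction coordinates are required for `jR` because the
annotation is taken as authoritative (novel-junction discovery is assumed
disabled upstream).  Introns with zero total support report `NA`, and a
`min_support` threshold can suppress low-confidence rows (e.g. tRNA introns
in libraries size-selected above the spliced tRNA length) — exclusion is a
data property, not hard-coded.

### Editing efficiency

At each annotated site the plus-strand base reported by every overlapping,
non-gap read position with base quality >= `min_base_quality` (default 0;
upstream reads are typically already quality-trimmed) is tallied.  Deletions
and reference skips spanning the site count toward `total_depth` but toward
none of the four base counts.  Efficiency is the edited fraction:

* plus-strand (C) site: `T / (T + C)`
* minus-strand (G) site: `A / (A + G)`

Sites with zero informative depth report `NA`, never 0 — "unobserved" and
"unedited" are different statements.  The pileup aggregates both strands, as
pileup-based variant tallying conventionally does; at sites with substantial
antisense transcription the antisense reads carry the genomic base and
dilute the estimate downward (on the default simulation, a 5% antisense
fraction depresses a fully edited site to ~0.95).  Strand-filtering the
pileup would remove this bias at the cost of diverging from the classic
pileup semantics; the aggregate behaviour is kept and documented.

### Condition comparison

`compare_conditions` joins two metric tables on feature id, drops NA rows
pairwise, and reports per-feature `log2(b/a)` (NA where either value is zero
unless a pseudocount is requested — a silent pseudocount would fabricate
fold changes at zero-coverage features), distribution summaries, and
two-sample t-tests.  Both the pooled-variance ("Student") and Welch variants
are reported, since "Student's t-test" in the literature is ambiguous about
the variance assumption.

## Synthetic data generator

The generator emulates a stranded single-end chloroplast library over a toy
plastome: 12 genes on alternating strands (eight 2-exon genes, one 3-exon
gene, three single-exon genes; ~15 kb genome), 10 introns of 200–300 nt, 12
editing sites spanning edited fractions 0–1, a 5% antisense and 3%
intergenic read population standing in for pncRNAs, 80 nt reads at constant
Q40, and 4,000 reads per gene (~50k reads) by default.

Reads are emitted as real SAM records (written and re-read through pysam) so
the analyses exercise the production parsers.  Per read, the generator first
draws a molecule's splice pattern (each intron independently spliced with
its configured probability), then a start position uniform over the
molecule: starts inside a spliced-out intron are rejected and redrawn, which
makes read density uniform over each transcript and the junction/boundary
read proportions consistent with the configured spliced fraction.  Sense
reads covering an editing site of their own gene carry the edited base
(C→T on the plus strand, G→A on the minus strand) with the site's configured
probability; antisense and intergenic reads are contiguous and unedited.

Every stochastic decision is recorded at emission into a truth table
(per-intron `jR/liR/riR`, per-site edited/unedited/depth, per-feature read
counts, per-nucleotide stranded coverage), so pipeline counts can be checked
for *exact* agreement, not statistical closeness.  The generator does not
model sequencing error, quality variation, fragment-length distributions,
PCR duplicates, or the inverted repeat's multi-mapping; passing tests
therefore demonstrate counting and formula correctness on clean data, not
robustness to base-calling noise or mapping ambiguity.

For parameter-recovery studies two focused simulators are used instead of
the full library: `simulate_junction_reads` places every read across one
intron shorter than the read length, so each read is informative (spliced →
junction read; unspliced → both boundaries) and the SE estimator is exactly
binomial in the spliced count, making the exact 99% binomial-interval check
well-posed; `simulate_site_reads` does the analogous thing for one editing
site.  Recovery is assessed over 100 replicates at depth 200 per feature.

## Numerical choices

* Percentages round half-up to one decimal; RPKM, normalized coverage, SE
  and editing efficiency are written with 4 decimals; counts as integers.
* Undefined ratios (`jR+liR+riR = 0`, zero informative pileup depth, zero
  mappable reads) are `NA`/errors, never silently 0.
* Ties/degenerate inputs: abutting exons yield no intron; zero-length
  intervals are rejected at construction; reads extending past the genome
  end raise (circular-genome wraparound is out of scope).
* Determinism: all simulation randomness flows from one integer seed through
  `numpy.random.default_rng`; pipeline outputs are byte-identical across
  reruns on the same inputs.

## Problem sizes

The bundled test suite and the acceptance script run on the default
simulated library (~50,400 reads, 15 kb genome, 12 genes / 10 introns / 12
editing sites) and on 100-replicate recovery simulations at depth 200;
the complete simulate→write→parse→analyze round trip takes a few seconds on
one CPU.

## Replication workflow for real libraries (optional, not self-contained)

The biological observations this toolkit is designed to expose on real data —
e.g. heat-stress intron accumulation, collective splicing and editing
reductions, per-site editing heterogeneity — require the original public
libraries (SRA accession SRP028304, plus the other published libraries in
the alignment-rate table) and an external splice-aware aligner, and are
therefore *not* recomputed by this repository's tests.  To replicate:
quality-trim reads (Q>30, length >= 60), align to the TAIR10 genome with a
splice-aware aligner allowing two placements (for the inverted repeat) and
novel junction discovery disabled, then run
`plastidseq run -a all -b accepted_hits.bam -n ChrC ...` per library and
`plastidseq compare` (or `compare_conditions`) between conditions.  Only the
desk-checkable layer — the mapped/mappable percentages recomputed from the
published read counts, the formulas, and simulated-data truth agreement — is
asserted by the test suite and the acceptance script.
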