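# Methods

`landvar` re-implements, as a tested pipeline, the genome-wide variation
characterization workflow used when a single deeply resequenced genotype
(here modelled on a maize landrace) is compared against a reference
genome: reference gene-set filtration, variant call quality filtering,
functional-effect annotation of SNPs and short InDels, detection of
SNP-free regions, novelty calling against a known-variant database, and
windowed density scanning of chromosomes and QTL intervals.  Because the
raw sequencing reads of such a study are out of scope (read mapping and
the variant callers themselves are upstream of this pipeline), every
stage is exercised on synthetic genomes carrying planted variants with
ground-truth labels.

## Coordinate model and variant classes

Positions follow GFF3/VCF (1-based inclusive); interval tracks and
genome windows follow BED (0-based half-open).  Conversion happens only
inside `genome_io`.  Variants are classed by the length of inserted or
deleted sequence: 0 bp → SNP, 1–5 bp → InDel, >5 bp → SV.  InDels use
VCF-style anchored alleles and are left-aligned on read, so overlap
tests are unambiguous: a deletion at anchor `pos` affects the interval
`(pos, pos + length]`.  Variants on chromosomes absent from the genome
FASTA are kept, reported in an "unknown" bucket of the per-chromosome
table, but never effect-annotated.

## Gene filtration

Four rules, applied in order: (1) CDS < 150 bp removed; (2) internal
stop codon (any stop before the final codon of the spliced CDS) removed;
(3) one transcript per locus, the longest CDS kept; (4) overlapping gene
spans resolved by keeping the longest CDS.  "Longest" ties break on the
lexicographically smallest transcript id so output is deterministic.
Rule 4 compares spans regardless of strand (the conservative reading;
the overlap test is a function argument away from being strand-aware).
A terminal stop codon is not required for retention.

## Variant quality filtering

SNPs pass when caller quality > 20 (strict), supporting depth > 2
(strict, per the wording "higher than 2"; configurable), copy number
≤ 1.5 (1.5 itself passes; values above it indicate repeat-induced
artifacts and are excluded), and no other *called* SNP — pass or fail —
lies within 5 bp.  Both members of a close pair are moved out of the SNP
set with reason `proximity`; InDels do not trigger SNP proximity.
Rejection reasons use the first failing criterion in the order quality,
depth, proximity, copy number.  InDels pass at support strictly above
1/3 of mapped reads; SVs pass at depth ≥ 3 (a stated minimum, hence
inclusive).

## Effect annotation

Each variant gets exactly one region class against the filtered,
non-overlapping gene set: CDS, 5′/3′ UTR, intron (inside the gene span
but outside exons), else intergenic.  Deletions are classified per
deleted base with precedence CDS > 5′UTR > 3′UTR > intron.

Coding SNPs are classified at the codon level: the affected codon is
located in the spliced CDS (strand-adjusted), the alternate base is
substituted, and both codons are translated.  Same amino acid →
synonymous; otherwise non-synonymous, with large-effect flags:

* **premature stop** — alternate codon is a stop before the terminal codon;
* **stop lost** — terminal stop codon becomes sense;
* **start lost** — codon 1 ATG altered (every substitution of ATG is
  non-synonymous, so there is no ambiguity);
* **property change** — reference and alternate amino acids fall in
  different physicochemical classes of the four-way partition
  hydrophobic {A,V,L,I,M,F,W,P,G,C}, negative {D,E}, positive {K,R,H},
  polar uncharged {S,T,N,Q,Y}.  This is a standard textbook partition
  and is configurable; the stop symbol is deliberately unmapped, so a
  stop gain/loss never doubles as a property change.

Splice classification is positional and strand-symmetric: the
*essential* splice site is the first 2 or last 2 bp of an intron; the
*splice region* adds 1–3 bp into any intron-adjacent exon end, so
essential sites are a subset of the splice region and counts of the
latter subsume the former (mirroring how splice-site taxonomies are
usually tabulated).  A variant whose region is intron or CDS may still
carry splice flags.  Large-effect flags are recorded independently —
one SNP can carry several — and only for SNPs; coding InDels are
classified frameshift (length not divisible by 3) or in-frame only.
Codons containing N translate as undetermined and are excluded from the
synonymous/non-synonymous partition.

Each annotation reduces to a single descriptive label via a fixed
precedence (essential splice > splice region > start lost > stop lost >
premature stop > InDel consequence > property change > other
non-synonymous > synonymous > region); this is the label the planted
ground truth is checked against.

## Region scanning

Adjacent-SNP distances are computed per chromosome and binned
(<100 bp, 100 bp–<1 kb, ≥1 kb), with fractions reported against the
total SNP count.  SNP-free regions are inter-SNP gaps of strictly more
than 10 kb (bases strictly between the flanking SNPs; chromosome ends do
not qualify).  Genes fully contained in such regions are candidates,
minus genes overlapping any repeat interval and genes with at least one
unsequenced base (zero or missing coverage) in their span — "any zero
base" rather than "fully uncovered" better matches the intent of
excluding unsequenced genes, and is a parameter away from the stricter
reading.

Density scans tile each chromosome with fixed windows (1 Mb by default;
the analysis scripts use 100 kb on the 1-Mb synthetic chromosomes so
each chromosome holds ten windows); terminal short windows are
normalized by their true length so per-Mb thresholds remain comparable.
Default call thresholds per Mb: SNPs high >3,500 / low <500; novel SNPs
>500 / <20; InDels >250 / <10; SVs high >80 (no low bound).  Adjacent
qualifying windows merge into one region call, so the number of
"regions" depends on this merge rule and is comparable only
qualitatively across studies.  QTL comparison tiles 10-kb windows across
each QTL interval, computes per-genotype density, and reports the
focal genotype's densest window with its overlapping genes.

## Novelty calling

A SNP matching the known-variant database on (chromosome, position,
alternate allele) is known; of the rest, SNPs inside repeats are
repeat-excluded (detection there is unreliable); the remainder are
novel.  The three sets partition the input, and repeat exclusion applies
only to novelty calling, never to the main SNP set.  Allele-aware
matching is the default because haplotype-map entries are
allele-specific; position-only matching is available.

## Synthetic data: what it emulates, and what it does not

The generator plants genes with canonical structure — ATG start, single
terminal stop, GT..AG introns with splice junctions inside the CDS (so
UTRs stay contiguous and every splice label is constructible), 60–200
codon CDS, 60–200 bp UTRs, 2–5 exons, alternating strands — and builds
each effect variant directly from that structure (e.g. a premature-stop
SNP picks a sense codon one substitution from a stop).  Planted variants
keep ≥6 bp spacing so the proximity filter never removes them, and
InDels are planted in left-aligned form.  A generation-time self-check
re-annotates everything and refuses to emit a dataset whose labels do
not round-trip.

Default conditions emulate the genome-wide statistics of a deeply
resequenced maize landrace: 2 chromosomes × 1 Mb; per-100-kb-window SNP
rates cycling through 4,000 / 1,500 / 300 per Mb (covering the >3,500
high and <500 low regimes around a ≈1,600/Mb average); 103 InDels/Mb
and 19 SVs/Mb of intergenic background with decreasing length
distributions (mononucleotide-dominated for InDels, geometric-like decay
for SVs, insertion fraction 0.46); 62.8% of SNPs placed in the known-SNP
database; 20% repeat coverage; 2% uncovered genome; 20 planted variants
per effect label; and a quarter of genes held variant-free inside a 6-kb
SNP-free buffer so that >10-kb SNP-free regions containing genes exist
(their count, ~10 per run, emulates conserved loci at this scale).
Everything is deterministic given the seed, and outputs are
byte-identical across runs.

The generator does **not** model read-level noise, mapping bias,
genotype errors, linkage structure, population history, nested gene
models, non-canonical splice sites, or Ns in the reference.  Passing
tests therefore demonstrate the correctness of the *classification and
bookkeeping logic* under clean calls, not robustness to caller noise —
which the quality filters are designed to absorb but which is not
simulated here.

## Numerical choices

Percentages are computed from the counts present in the same report and
rounded half-up at the displayed precision (2 decimals, with a 1-decimal
variant).  Densities per chromosome are reported to 0 decimals.  All
writers sort deterministically; reports are byte-identical across
re-runs.  Ties in gene ranking break on gene id; ties in "longest
transcript/gene" break on transcript id; the QTL top window takes the
leftmost maximal window.

## Problem sizes

The default study conditions (2 × 1 Mb, ≈4,000 planted variants, 40
genes) were chosen so a full pipeline run takes a few seconds and the
whole test suite well under a minute on one CPU, while every effect
class and density regime is still represented at ≥20 instances.  The
acceptance script (`scripts/acceptance.py`) recomputes all headline
quantities from scratch at these sizes.

## Known limitations

* The large-effect taxonomy overlaps by design (flags are independent),
  so category counts may sum past the number of flagged SNPs.
* SVs receive region assignment only; consequence calling for SVs and
  splice/start/stop evaluation for InDels are out of scope.
* High/low density "region" counts depend on the window-merge rule.
* Known-database matching assumes one shared coordinate system; no
  lift-over is performed.
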