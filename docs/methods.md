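# Methods

This note documents the models, conventions and design choices behind
circscape, and what its synthetic cohorts do and do not emulate.

## Coordinate and format conventions

GTF coordinates are 1-based inclusive; BED intervals 0-based half-open;
SAM positions 1-based (pysam exposes 0-based starts internally). Introns
are the gaps between consecutive exons of a transcript; linear junctions
are the ordered exon pairs those gaps connect. Both are deduplicated by
exact genomic coordinates across transcripts of a gene, so "unique
junction" means unique coordinates, not unique transcript.

## Confident catalog

A back-splice candidate is accepted when both boundaries match exon
boundaries of a *single* gene within a tolerance of 1 bp (each end
separately; discrepancies are recorded and later imposed on the assembled
circRNA sequence). Unstranded candidates are tried on both strands; ties
resolve by smaller total boundary discrepancy, then lexicographic gene id.
The cohort expression filter keeps a candidate if it is detected (≥ 1 BSJ
read) in at least ⌈0.25·N⌉ of N samples, or supported by ≥ 20 reads in at
least 3 samples. "Detected" uses a one-read threshold because the
read-support branch already carries the stringency; the ceiling makes the
25 % rule attainable for any cohort size.

## Junction pseudo-reference and counting

Each confident circRNA yields a 160-nt back-splice contig: the last 80 nt
of the donor exon followed by the first 80 nt of the acceptor exon,
strand-oriented, breakpoint in the middle. The symmetric 80/80 split
maximizes the smaller of the two overhangs; circRNAs whose donor or
acceptor exon is shorter than 80 nt are dropped as untrimmable. Linear
contigs keep full exon lengths so that reads without a back-splice prefer
them. Genes without any linear junction drop their circRNAs (no linear
denominator exists for them).

A fragment counts once per contig when at least one mate's primary
alignment covers the breakpoint window (± 5 nt by default — an explicit,
testable overhang rule), has MAPQ ≥ 13, and the pair is oriented first
mate reverse / second mate forward, matching a stranded dUTP library.
Secondary and supplementary records are ignored; no insert-size window is
imposed. A linear junction is *external* to a circRNA when neither of its
exons lies inside the back-splice span (1 bp slack); externality is kept
per (circRNA, junction) pair because a gene can host several circRNAs.

## Ratios, productive genes, dispersion

Within a gene and sample, BSJ counts are averaged across circ isoforms and
linear-junction means across the same isoforms before the circ:linear
ratio is formed; genes with zero linear expression carry no ratio. Group
comparisons pool gene × sample ratio records per group and use a two-sided
Mann–Whitney test (exact for tie-free pooled sizes ≤ 20, else normal
approximation with tie correction); distributions are exported as ECDF
point sets. A gene is circRNA-productive when its expressed circ-isoform
count divided by its expressed mRNA-isoform count strictly exceeds 1.2
(isoform counting, not abundance; a circ isoform counts with ≥ 1 BSJ read
in ≥ 1 sample, an mRNA isoform with ≥ 1 TPM in ≥ 1 sample).

The Fano factor is sample variance (n−1 denominator) over sample mean of
counts across samples, per isoform, averaged within gene. It is 1 under
Poisson (constitutive) dynamics, below 1 under tight regulation; the
scale property (counts × c ⇒ Fano × c) and Poisson calibration are both
asserted in tests.

## Tandem specificity test

Features reaching ≥ 1 CPM in ≥ 30 % of focal-cohort samples are tested
with two one-sided (cohort-greater) Mann–Whitney tests against two control
cohorts. One-sided, because the procedure seeks transcripts elevated in
the focal cohort; a two-sided test would also flag depleted ones. BH
adjustment is applied separately within each test across features, and the
α = 0.001 threshold gates the *adjusted* values — the stricter of the two
possible readings; unadjusted p-values are also reported. The combined
p-value is the plain sum of the two unadjusted p-values; it can exceed 1
and is reported as-is for ranking only.

## Sequences and introns

The putative circRNA sequence splices all annotated gene exons inside the
back-splice span; overlapping exon variants resolve to the longest
(leftmost on ties), and the candidate's own boundaries replace the
terminal exon boundaries so ±1 bp discrepancies survive into the sequence.
The control sequence splices all exons strictly 5' of the acceptor and,
separately, strictly 3' of the donor, keeps the longer product, and trims
a length excess symmetrically — ⌊excess/2⌋ from the start, ⌈excess/2⌉ from
the end (the odd nucleotide goes to the end by convention). Controls
shorter than the circRNA on both sides are flagged and excluded from
length-matched analyses.

Flanking introns are the introns immediately adjacent to the circle
boundaries, taking the longest annotated variant of each adjacent gap
(1 bp slack); introns shorter than 15 nt are ignored. Control introns are
chosen greedily — longest first, skipping anything overlapping the circle,
the flanks, or previously chosen controls — until their cumulative length
reaches the cumulative flank length, and are kept as independent intervals
(no splicing, to avoid artificial intron–intron junctions). Repeat overlap
(≥ 1 bp) of flank vs control introns is tested per stratum (upstream,
downstream, combined) with two-sided Fisher tests.

## Motif scanning

PWM entries whose matrix length disagrees with their consensus length are
dropped, as are motifs shorter than 6 positions; entries with identical
matrices merge into one record. Scores are log2 odds against a zero-order
background (single-nucleotide frequencies of the target sequences), with
motif probabilities floored at 1e-3 so zero cells stay finite. The null
score distribution is computed exactly by dynamic programming over
positions with scores discretized to 1e-3; the cutoff is the smallest
attainable score with tail probability below the p-value threshold
(default 1e-4). Both orientations are scanned, each with its own cutoff
(the null distribution of a reverse-complement motif differs under an
asymmetric background). A consequence of exact thresholds: a sharp 6-mer
under a uniform background has a best attainable tail of 4⁻⁶ ≈ 2.44e-4 and
can never match at 1e-4 — this is reported, not silently patched; the
cutoff is configurable. Dinucleotide-preserving controls use the
Altschul–Erikson shuffle (uniform over Eulerian arrangements, preserved
termini), and sequence-level enrichment is a one-sided Fisher test on
has-hit counts with BH correction — the simplest documented enrichment
mode, fully reproducible without external motif tooling.

## Cohort statistics

The proliferative index is the median over signature genes of
log2(TPM + 1); the +1 pseudocount handles zero TPMs. Samples cluster on
the 1-D index (Euclidean, complete linkage, cut at two clusters labeled by
mean). Expression heatmap clustering divides each sample by its read sum,
z-scores features across samples, and uses Manhattan distance for samples
and Canberra for features, complete linkage throughout (one convention,
configurable). RBP–circRNA structure uses Spearman correlations
(average-rank ties) clustered by Euclidean distance of the correlation
vectors; cluster-pair counts are normalized by the product of cluster
sizes.

Size factors are median-of-ratios: reference = per-gene geometric mean
over samples (genes with any zero excluded), factor = per-sample median of
count/reference, computed in linear space. The factors come from *gene*
counts and are applied to circRNA counts: deriving them from the circRNA
counts themselves would treat a genuine global shift in circRNA output as
a depth artifact and erase it — the package's defining normalization
contrast, asserted on synthetic cohorts. Percentile grouping uses linear
interpolation between order statistics with strict inequalities
("above"/"below"); per-feature differences use a two-sided rank test on
size-factor-normalized counts (a deliberate, documented surrogate for a
negative-binomial GLM — the bespoke content here is the normalization
rule, not the regression machinery), BH at 5 % FDR, with a χ² test of the
up/down balance against 50:50. Features with fewer than 5 summed reads are
dropped first.

## Synthetic cohorts

`SimSpec` defaults define the simulated study conditions: 100 genes
(6–9 exons of 100–250 nt; introns 400–1200 nt), 40 % of genes hosting one
circRNA, two groups of 20 samples, circRNA means multiplied by 0.5 in the
suppressed group, negative-binomial dispersion 0.2 (a typical bulk RNA-seq
value), gene-level means lognormal around 200 counts, circRNA baselines
around 10 % of that, log-normal library-size factors (σ = 0.3), 10
cohort-specific circRNAs at 8-fold. Host genes of circRNAs receive
uniformly long introns (twice a per-gene draw from the intron range), so
flanking introns of circRNAs are systematically longer than control-gene
introns, and guarantee enough non-flank intronic material that control
intron selection always reaches the cumulative flank length. A fixed
300-nt Alu-like sequence is planted with probability √f in circ-flanking
introns and f² elsewhere (f = `alu_seed_fraction`): both probabilities
reach 1 at f = 1 and flanks dominate at every intermediate f. Reads are
emitted directly as SAM records spanning the junction breakpoint (MAPQ 60,
proper orientation), plus labeled decoy classes (low MAPQ, secondary,
wrong orientation, non-spanning) for counting-rule tests; FASTQ export is
available for users who want to run a real aligner. Every output is a
deterministic function of the spec, including its seed.

What the generator does **not** emulate: sequencing errors, splice-aware
alignment ambiguity, isoform-level transcript variation beyond a second
exon-extended transcript in a fifth of non-circ genes, batch effects
between cohorts, and biological covariance between circRNA and host
expression (baselines are drawn independently, consistent with the weak
circ–mRNA coupling seen in tumor cohorts). Passing tests therefore
demonstrate correctness of the counting and statistical rules under
controlled conditions, not robustness to alignment artifacts in real data.

A caveat worth stating: with per-gene baseline heterogeneity, the pooled
gene × sample ratio comparison is *conservative* under the null (records
from one gene are shifted together in both groups, shrinking the rank
statistic's variance relative to the iid assumption), so null p-values
concentrate above ~0.3 rather than being uniform. The planted suppression
is nevertheless detected essentially always at the default effect size.
Users wanting calibrated null behavior should compare per-sample summary
ratios instead of pooled records.

## Problem sizes in tests

The suite runs on cohorts of 20–40 genes (SAM round trips) up to 750 genes
(specificity), 20-seed repetitions for stochastic recovery checks, and
exhaustive enumeration oracles for small statistics (rank tests to
n₁+n₂ = 10, Fisher tables to total 40, PWM words to 4⁸). These sizes give
stable pass/fail behavior at interactive runtimes.
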