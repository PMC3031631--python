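# Methods

This note documents the models and procedures implemented in `seqbias`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Coordinates and read anchoring

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
and SAM (1-based) are converted at file boundaries only. Every scoring
operation anchors a read at its 5′-most genomic coordinate — for a
minus-strand read, the *highest* position it covers (for a reverse-strand
SAM record, `reference_end − 1`). In nascent-transcription data this
coordinate marks the position of the transcriptionally engaged
polymerase; using one anchor everywhere keeps pileups, mappability
denominators and junction projections consistent.

Alignment scores are canonicalized to higher-is-better on load; adapters
negate penalty-style scores. Uniqueness of a SAM record is
mapper-specific and therefore configurable (a tag such as NH, or a MAPQ
threshold; default MAPQ ≥ 1).

## Leading k-mer reweighting

Given a pool of uniquely mapped reads, the weight of a read beginning
with k-mer `m` is `(1/4^k) / freq(m)`, where `freq` is estimated from the
same pool (cross-pool weights are allowed; reads whose k-mer is absent
then contribute zero and are counted). The normalization constant `1/4^k`
is chosen so that a uniform pool gives weight 1 everywhere and total mass
is conserved when all k-mers occur; any positive rescaling would leave
every fold-change unchanged, so the choice is observationally neutral.
Two exact identities follow and are enforced by tests: the weighted mass
per observed k-mer is identical across k-mers, and the track total equals
the pool size when all `4^k` k-mers occur. Reads with N within the first
k bases are excluded from the frequency estimate and counted.

The splice-site peak is quantified as a fold-change per expression bin:
the mean score at a single consensus-A position (acceptor −2, the A of
the 3′ss AG; or donor +3, the A of the 5′ss GTA) divided by the mean
score over intronic background offsets −200..−100 of the upstream intron
(acceptor) or +100..+200 of the downstream intron (donor), clipped to the
intron when shorter. Bins with fewer than 10 quintets are reported but
flagged. The SE of a fold is propagated from the per-quintet SEMs of peak
and background; when the two consensus-A sites measure the same injected
bias they may be pooled (ratio of pooled means), halving the variance.

## Mappability

A plus-strand position p is assessed on the window [p, p+L); a
minus-strand position p on the reverse complement of (p−L, p]. The
exact-mode builder enumerates every window of both strands (the plus
windows plus their reverse complements) and marks a position mappable iff
its window occurs exactly once in that combined multiset. Two
consequences are deliberate:

- a window equal to its own reverse complement occurs on both strands of
  its single locus and is therefore unmappable (no special case needed);
- windows containing N never match anything and are unmappable without
  destroying the uniqueness of other windows (N = unknown base under
  exact-match semantics).

Mismatch-tolerant uniqueness (Hamming distance ≤ 1 or 2, where *any*
second window within the distance destroys uniqueness) is provided as a
brute-force all-pairs mode capped at 20 kb of genome by default; beyond
that the quadratic comparison is not worth its cost and exact mode is the
supported path.

Region densities divide the summed score over a region by its number of
mappable positions; a region with zero mappable positions yields an
explicit undefined flag, never a silent zero.

## Quintets, binning, metagenes, and the four-region test

The unit of exon/intron comparison is the quintet: an internal exon, its
two flanking introns, and two flanking internal exons. Filters, applied
in order with a per-filter attrition report: all five intervals ≥ 32 nt;
central exon ≥ 1 kb (edge-to-edge, both strands — the most conservative
reading) from every annotated transcription start or end site; no
interval overlapping an RNA-gene record; optionally the upstream exon
≥ 1 kb from any TSS; duplicate central-exon coordinates kept
first-encountered (survivor identity does not affect coordinate-level
analyses). Isoform deduplication by cluster uses a seeded RNG for
reproducibility.

Quantile binning orders features by value (stable order breaks ties) and
splits them into groups whose sizes differ by at most one; features
without a value are dropped and counted.

Metagene profiles average a score or mappability track at offsets
−flank..+flank around anchors, flipping minus-strand features so positive
offsets point downstream in transcript orientation. Offset 0 is the first
exonic base at a 3′ss anchor and the last exonic base at a 5′ss anchor
(so "−2" and "+3" are intronic consensus positions). When a mappability
mask is supplied, unmappable positions leave both the numerator and that
offset's denominator. The error statistic is the SEM, defined where at
least two features contribute.

The association test compares per-quintet mean values across bins in four
regions — the 200 intronic nt upstream of the exon, the first and last
100 exonic nt, and the 200 intronic nt downstream (clipped to short
features) — with a tie-corrected Kruskal–Wallis rank test per region; the
summary p-value is the *maximum* (least significant) of the four. Groups
with fewer than two members are excluded with a warning.

## Junction libraries and the contamination model

Each junction sequence concatenates the last 31 nt of the donor exon with
the first 31 nt of the acceptor exon in transcript orientation, with an
injective offset→genome coordinate map (junction-local offset 0 maps to
`donor_end − 31` on plus-strand transcripts). Junction alignments are
accepted iff they are unique in the library, sense-strand, cover at least
`min_overlap = 4` aligned nt on each side of the boundary, and either
have no genomic alignment or strictly beat it (equal scores are rejected
— the conservative reading). Accepted reads are projected to the genomic
coordinate of their junction-local 5′ offset and then enter the score
pipeline like any genomic read.

The analytic model: `total` reads uniform over a pre-mRNA whose introns
are r-fold longer than its exons put `total/(1+r)` reads in exons; adding
C exon-only contaminants raises exonic density by `100·C/(total/(1+r))`
percent while intronic coverage is essentially unchanged. The measured
counterpart (`estimate_contamination`) is the mappability-normalized
central-exon density versus the mean of the two flanking-intron
densities, overall and per expression bin, with two-sided two-sample
Student's t-tests across per-quintet densities.

Geometry of the valley: a read of length R starting in the last R−1 nt
of an exon crosses the junction and cannot map to the genome, so before
projection the contaminant-free gap spans the terminal R−1 positions.
After projection the only unrecoverable starts are the `min_overlap − 1`
positions closest to each junction edge (overlap too small on one side),
a ~3/28 deficit at the defaults — visible only below sampling noise in
practice.

## The synthetic generator

The generator is the study-condition definition, not a convenience
fixture. Defaults: one contig; 20 genes of 7 exons; exon 150 nt, intron
1500 nt (introns an order of magnitude longer than exons, the regime in
which the contamination arithmetic is dramatic); random strands;
intergenic spacers of 300 nt; log-expression ~ Normal(0, 1) (genes are
sampled proportionally to exp(expression)); read length 32. Optional
features: per-gene length jitter; duplicated segments appended after the
genes (each copy recorded, producing known unmappable windows);
snoRNA-like single-exon genes planted wholly inside host introns.

Reads are drawn per candidate: with probability h the read starts at the
transcript's first base (the non-hydrolysis mechanism — nascent RNA, so
the unspliced sequence); otherwise with probability c uniformly from the
spliced mRNA (contaminant; junction-spanning sequences arise naturally);
otherwise uniformly from the unspliced pre-mRNA. The first-base bias is
injected by rejection sampling against the multiplier of the candidate's
first as-sequenced base, so the bias is *in the data*, not applied post
hoc; the acceptance probability gives the closed form
P(start on A) = m·f_A/(1 − f_A + m·f_A) used by the tests. An optional
uniform error rate miscalls one base per affected read to exercise the
read filters. All draws derive from the single config seed.

**Bias-probe genomes** (`plant_bias_probes=True`) make the splice-peak
experiment exactly calibrated: every intron carries the GTA..AG consensus
(so acceptor −2 and donor +3 are A in every quintet), the fold-change
background windows are drawn from {C, G, T} only, and the remaining gene
positions are drawn from exact-count pools that rebalance each gene to
uniform single-base composition. Consequently the expected unweighted
fold equals the A multiplier exactly, and the k=1-weighted fold is
exactly 1. The trade-off: the genome is balanced per *base*, not per
*dimer*, so k=2 reweighting re-distorts the planted AG consensus and is
not expected to improve on k=1 there (it still reduces the fold relative
to the unweighted track). Geometries with very short exons relative to
the planted windows cannot be rebalanced; the generator raises an error
rather than producing a skewed genome.

The exact unique mapper reports a read iff its sequence or reverse
complement matches exactly one genomic window across both strands
(counted jointly, so palindromic matches are non-unique), which makes it
provably consistent with the mappability track at the same read length.

What the simulations do *not* emulate: sequencing quality scores, indels,
fragment-length effects, hexamer-priming sequence dependence beyond the
first base, alternative isoforms, and overlapping genes. Passing tests
therefore demonstrate the correctness of the corrections under the
modeled mechanisms, not their sufficiency for any particular real
library.

## Problem sizes used by the packaged experiments

- Splice-peak experiment: 14 genes × 30 exons (exon 60 / intron 250 nt,
  308 quintets), 200,000 reads, A multiplier 2.0, single expression bin;
  the two consensus-A sites are pooled for the headline fold.
- Contamination experiment: 16 genes × 7 exons (exon 150 / intron
  1750 nt, so the total intron:exon ratio is exactly 10), 20,000 reads,
  c ∈ {0, 0.02, 0.05}, five seeds; excess measured on central exons vs
  flanking introns, valley on the terminal 28 exonic nt.
- Mappability validation: exact tracks against an all-pairs oracle on
  fifty random 10-kb genomes at read length 12, with planted N runs and
  duplicated blocks.
- Kruskal–Wallis calibration: 1,000 null repetitions over 60 quintets in
  5 bins; per-region rejection rate compared with the nominal 5% level.

## Known limitations

- Exact-mode mappability holds all window views in memory; fine for the
  tens-of-megabase scale the toolkit targets, not for mammalian genomes
  on a laptop.
- Mismatch-tolerant mappability and the exact mapper are brute-force by
  design (oracles, not production aligners); real data should be aligned
  externally and imported via SAM/BAM or the minimal TSV dialect.
- The contamination estimate attributes the whole exon-vs-intron excess
  to contamination; genuine exonic polymerase enrichment would be
  conflated with it, which is precisely why the junction-read and
  ncRNA-level diagnostics exist.
- Non-hydrolysis enrichment is detected (metagene spike at feature
  starts), not corrected; no removal procedure is defined.
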