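# seqbias

Detection and removal of read-start biases in next-generation sequencing
data, for anyone who summarizes uniquely mapped short reads over genomic
regions — RNA-seq, ChIP-seq, and especially nascent-transcription (GRO-seq)
analyses that compare exons with introns.

Four biases are covered:

1. **Nucleotide-per-cycle bias.** Illumina pools over-sample certain bases
   at the first sequencing cycles (in GRO-seq, ~42% of reads begin with A).
   When each genomic position is scored by the number of reads starting
   there, any single A becomes a ~2-fold "peak" — exactly what happens at
   the consensus-A positions −2 of the 3′ splice site (**A**G) and +3 of
   the 5′ splice site (GT**A**). The correction weights each read by the
   inverse frequency of its leading k-mer,

   `score(pos) = Σ_reads (1/4^k) / freq_reads(kmer(read))`,

   which makes the weighted mass contributed per observed k-mer exactly
   equal (with k = 0 the score is the plain read-start pileup).

2. **Mappability bias.** A position can receive a uniquely mapped read only
   if the read-length window anchored there occurs exactly once across
   both genome strands. Exons are more mappable than introns, so raw
   densities are confounded. `seqbias` builds exact per-strand
   mappability tracks by exhaustive window enumeration (a brute-force
   Hamming-tolerant mode exists for small genomes) and computes densities
   as Σ score / number of *mappable* positions.

3. **mRNA contamination.** In pre-mRNA-level experiments, a few percent of
   spliced-mRNA contaminant reads inflate exonic densities dramatically:
   with introns 10× longer than exons, 100,000 uniform reads put only
   ~9,000 in exons, so 2,000 exon-only contaminants (2% of the pool) raise
   exonic density by ~22% while intron coverage barely moves. Contaminant
   reads spanning exon–exon junctions cannot map to the genome at all,
   carving a "valley" over the last ~31 exonic nt. The toolkit builds
   62-nt junction libraries (31 nt either side of each boundary), selects
   junction reads (≥4 nt overlap each side, strictly better than any
   genomic alignment), and projects them back to genomic coordinates,
   eliminating the valley and exposing the contamination level.

4. **5′-end non-hydrolysis bias.** Reads starting exactly at transcript or
   ncRNA 5′ termini are over-represented because those ends require no RNA
   hydrolysis before sequencing. Metagene profiles anchored at feature
   starts detect the spike (detection only; no removal is defined).

A synthetic-data module generates genomes, annotations, and read sets with
all four biases injected at known levels (plus duplicated segments for
unmappable regions and intron-hosted snoRNA-like genes), together with a
brute-force unique exact mapper, so every stage is testable end to end
with no external downloads.

## Worked example

The analytic contamination model (exon-only contaminants over a genome
whose introns are r-fold longer than its exons):

```bash
$ seqbias predict --total-reads 100000 --ratio 10 --contaminating-reads 2000
{
  "exonic_before": 9090.90909090909,
  "intronic_before": 90909.09090909091,
  "exonic_after": 11090.90909090909,
  "pct_density_increase": 22.000000000000004
}
```

Of 100,000 uniform reads, ~9,091 land in exons; adding 2,000 exon-only
contaminants raises exonic reads to ~11,091, a 22% density increase, while
intronic coverage is essentially unchanged.

Creating and removing the splice-site peak with the library API — simulate
200,000 reads with a 2× A-start bias on a genome with planted splice-site
consensus, map them, and measure the peak at the acceptor −2 position over
the upstream-intron background (−200..−100):

```python
from seqbias import (SimulationConfig, simulate_genome, simulate_reads,
                     exact_unique_map, build_quintets, estimate_kmer_weights,
                     build_score_track, peak_fold_change)

config = SimulationConfig(seed=0, n_genes=14, exons_per_gene=30,
                          exon_length=60, intron_length=250, n_reads=200_000,
                          plant_bias_probes=True,
                          first_base_multipliers={"A": 2.0})
sim = simulate_genome(config)
reads = simulate_reads(sim)
mapped, _ = exact_unique_map(reads, sim.genome)
quintets, _ = build_quintets(sim.models)
for k in (0, 1):
    weights = estimate_kmer_weights(mapped, k)
    track, _ = build_score_track(mapped, weights)
    fold = peak_fold_change(track, quintets, "acceptor_minus2")[0]
    print(f"k={k}: acceptor -2 fold = {fold.fold:.2f} +- {fold.fold_se:.2f}")
```

prints

```
k=0: acceptor -2 fold = 1.96 +- 0.13
k=1: acceptor -2 fold = 0.98 +- 0.06
```

— the injected 2-fold peak appears in the unweighted track and vanishes
after k=1 inverse-frequency weighting.

The same pipeline is available from the shell: `seqbias simulate`,
`seqbias quintets`, `seqbias weights`, `seqbias score`,
`seqbias mappability`, `seqbias density`, `seqbias profile`,
`seqbias peakfold`, `seqbias kwtest`, and `seqbias junctions
build|select|project|estimate`. See `seqbias --help`.

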