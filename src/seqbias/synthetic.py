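"""Synthetic genomes, annotations, and biased read sets with ground truth.

The generator emulates the features the bias analyses depend on:
multi-exon gene models whose introns are an order of magnitude longer
than their exons, log-spread expression levels, reads drawn uniformly
from pre-mRNA, a configurable first-base sampling bias (injected by
rejection sampling, so the bias is in the data itself), a configurable
fraction of spliced-mRNA contaminant reads, a configurable probability
of reads starting exactly at transcript 5' ends (the non-hydrolysis
mechanism), and duplicated genomic segments that create unmappable
regions.  A brute-force unique exact mapper closes the loop as the
alignment oracle.

Bias-probe genomes (``plant_bias_probes=True``) additionally plant the
splice-site consensus (GTA..AG) so that acceptor -2 and donor +3 are 'A'
in every intron, draw the fold-change background windows from {C,G,T}
only, and rebalance the remaining gene positions to exact uniform
composition.  Under a first-base multiplier m for A this makes the
expected unweighted peak fold exactly m and the k=1-weighted fold
exactly 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._util import BASES, revcomp
from .core_io import Genome, GeneModel, MappedRead

_BASE_ARR = np.array(list(BASES), dtype="U1")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Geometry defaults follow the theoretical contamination model: introns
    an order of magnitude longer than exons (150 / 1500 nt).  All
    stochastic draws derive from ``seed`` alone.
    """

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: int = 7
    exon_length: int = 150
    intron_length: int = 1500
    length_jitter: float = 0.0  # lengths drawn uniformly within +/- this fraction
    intergenic_length: int = 300
    expression_mu: float = 0.0
    expression_sigma: float = 1.0
    read_length: int = 32
    n_reads: int = 100_000
    first_base_multipliers: Optional[Dict[str, float]] = None
    mrna_fraction: float = 0.0  # c: contaminant fraction among non-5'-end reads
    five_prime_enrichment: float = 0.0  # h: P(read starts at transcript base 0)
    duplicated_segments: Sequence[Tuple[int, int]] = ()  # (length, copies)
    ncRNA_in_introns: int = 0
    ncRNA_length: int = 120
    plant_bias_probes: bool = False
    error_rate: float = 0.0  # P(one random miscalled base per read)

    def validate(self) -> None:
        for name in ("mrna_fraction", "five_prime_enrichment", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.first_base_multipliers is not None:
            for b, m in self.first_base_multipliers.items():
                if b not in BASES or m <= 0:
                    raise ValueError("multipliers must be positive, over A/C/G/T")
        if self.exons_per_gene < 1 or self.n_genes < 1:
            raise ValueError("need at least one exon and one gene")
        if self.exon_length < 32:
            raise ValueError("exon_length must be >= 32 (junction flanks)")

    def multipliers(self) -> Dict[str, float]:
        mult = {b: 1.0 for b in BASES}
        if self.first_base_multipliers:
            mult.update(self.first_base_multipliers)
        return mult


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    origin: str  # pre_mRNA | mRNA | five_prime_start
    gene_id: str
    contig: str
    strand: str
    five_prime_genomic: int  # true genomic 5' coordinate
    transcript_pos: int  # start in pre-mRNA (or spliced mRNA) coordinates
    crosses_junction: bool = False
    error_cycle: int = -1


@dataclass
class SimulatedGenome:
    genome: Genome
    models: List[GeneModel]  # host genes
    ncrnas: List[GeneModel]
    duplicated_segments: List[Tuple[int, int]]  # genomic intervals of every copy
    config: SimulationConfig


def _jittered(rng: np.random.Generator, mean: int, jitter: float) -> int:
    if jitter <= 0:
        return mean
    lo = max(1, int(round(mean * (1 - jitter))))
    hi = int(round(mean * (1 + jitter)))
    return int(rng.integers(lo, hi + 1))


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.int8)


def _gene_codes_plain(rng: np.random.Generator, length: int) -> np.ndarray:
    return _random_codes(rng, length)


def _gene_codes_probed(
    rng: np.random.Generator,
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
) -> np.ndarray:
    """Transcript-oriented gene sequence with splice consensus, {C,G,T}
    background windows, and exact per-gene composition balancing."""
    total = sum(exon_lens) + sum(intron_lens)
    codes = np.full(total, -1, dtype=np.int8)
    is_bgw = np.zeros(total, dtype=bool)
    pos = 0
    parts = []  # (kind, start, length) in transcript orientation
    for i, el in enumerate(exon_lens):
        parts.append(("exon", pos, el))
        pos += el
        if i < len(intron_lens):
            parts.append(("intron", pos, intron_lens[i]))
            pos += intron_lens[i]
    A, C, G, T = 0, 1, 2, 3
    for kind, start, L in parts:
        if kind != "intron":
            continue
        codes[start : start + 3] = [G, T, A]  # 5'ss consensus; +3 is A
        codes[start + L - 2 : start + L] = [A, G]  # 3'ss consensus; -2 is A
        # background windows: transcript offsets +100..+200 from the intron
        # start and -200..-100 from the intron end, clipped to the intron
        donor_bg = range(99, min(200, L))
        accept_bg = range(max(0, L - 200), L - 99)
        for idx in set(donor_bg) | set(accept_bg):
            if codes[start + idx] == -1:
                is_bgw[start + idx] = True
    # exact-count {C,G,T} pool for the background windows
    n_bgw = int(is_bgw.sum())
    bgw_pool = np.array([C, G, T] * (n_bgw // 3) + [C, G, T][: n_bgw % 3], dtype=np.int8)
    codes[is_bgw] = rng.permutation(bgw_pool)
    # rebalance the free positions so the whole gene is uniform
    free = codes == -1
    n_free = int(free.sum())
    planted = np.bincount(codes[~free], minlength=4)
    target = np.full(4, total // 4, dtype=int)
    target[: total % 4] += 1
    need = target - planted
    if (need < 0).any() or need.sum() != n_free:
        raise ValueError(
            "bias-probe composition balancing infeasible for this geometry; "
            "use longer exons or introns"
        )
    free_pool = np.repeat(np.arange(4, dtype=np.int8), need)
    codes[free] = rng.permutation(free_pool)
    return codes


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate a genome, gene models, and ground truth; deterministic
    given the seed.  Genes are laid out on one contig separated by random
    intergenic spacers; duplicated segments are appended after the genes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pieces: List[np.ndarray] = []
    cursor = 0

    def push(codes: np.ndarray) -> int:
        nonlocal cursor
        pieces.append(codes)
        start = cursor
        cursor += len(codes)
        return start

    models: List[GeneModel] = []
    ncrnas: List[GeneModel] = []
    for g in range(config.n_genes):
        push(_random_codes(rng, config.intergenic_length))
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = [
            _jittered(rng, config.exon_length, config.length_jitter)
            for _ in range(config.exons_per_gene)
        ]
        intron_lens = [
            _jittered(rng, config.intron_length, config.length_jitter)
            for _ in range(config.exons_per_gene - 1)
        ]
        if config.plant_bias_probes:
            tx_codes = _gene_codes_probed(rng, exon_lens, intron_lens)
        else:
            tx_codes = _gene_codes_plain(rng, sum(exon_lens) + sum(intron_lens))
        gene_len = len(tx_codes)
        genomic = tx_codes if strand == "+" else (3 - tx_codes[::-1])
        gstart = push(genomic)
        # transcript-oriented part boundaries -> genomic exon intervals
        exons_tx = []
        pos = 0
        for i, el in enumerate(exon_lens):
            exons_tx.append((pos, pos + el))
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
        if strand == "+":
            exons = [(gstart + s, gstart + e) for s, e in exons_tx]
        else:
            exons = sorted(
                (gstart + gene_len - e, gstart + gene_len - s) for s, e in exons_tx
            )
        expr = float(rng.normal(config.expression_mu, config.expression_sigma))
        models.append(
            GeneModel(
                f"gene{g:03d}", "chr1", strand, gstart, gstart + gene_len,
                exons, "coding", expr,
            )
        )
    # embedded ncRNAs, wholly inside introns of host genes
    for k in range(config.ncRNA_in_introns):
        host = models[k % len(models)]
        introns = host.introns
        s, e = introns[len(introns) // 2]
        if e - s < config.ncRNA_length + 20:
            raise ValueError("intron too short to host an ncRNA")
        mid = (s + e) // 2
        ns = mid - config.ncRNA_length // 2
        ncrnas.append(
            GeneModel(
                f"sno{k:03d}", "chr1", host.strand, ns, ns + config.ncRNA_length,
                [(ns, ns + config.ncRNA_length)], "CD_box_snoRNA",
                float(rng.normal(config.expression_mu, config.expression_sigma)),
            )
        )
    push(_random_codes(rng, config.intergenic_length))
    duplicated: List[Tuple[int, int]] = []
    for length, copies in config.duplicated_segments:
        segment = _random_codes(rng, length)
        for _ in range(copies):
            push(_random_codes(rng, 150))
            start = push(segment.copy())
            duplicated.append((start, start + length))
    push(_random_codes(rng, 150))
    seq = "".join(_BASE_ARR[np.concatenate(pieces)])
    genome = Genome({"chr1": seq})
    for m in models + ncrnas:
        m.validate()
    return SimulatedGenome(genome, models, ncrnas, duplicated, config)


# ---------------------------------------------------------------------------
# Read simulation


class _TranscriptIndex:
    """Precomputed per-transcript lookups for fast read drawing."""

    def __init__(self, model: GeneModel, genome: Genome, read_length: int):
        self.model = model
        self.gene_len = model.tx_end - model.tx_start
        self.tx_seq = genome.fetch(
            model.contig, model.tx_start, model.tx_end, model.strand
        )
        self.spliced = model.spliced_sequence(genome)
        # spliced position -> genomic coordinate of that base
        blocks = []
        exons = model.exons if model.strand == "+" else model.exons[::-1]
        for s, e in exons:
            if model.strand == "+":
                blocks.append(np.arange(s, e))
            else:
                blocks.append(np.arange(e - 1, s - 1, -1))
        self.splice_map = np.concatenate(blocks)
        # exon index per spliced position, to detect junction-crossing reads
        self.exon_of = np.concatenate(
            [np.full(e - s, i) for i, (s, e) in enumerate(exons)]
        )
        self.read_length = read_length
        self.contig_seq = genome.contigs[model.contig]

    def genomic_pos(self, t: int) -> int:
        m = self.model
        return m.tx_start + t if m.strand == "+" else m.tx_end - 1 - t

    def pre_read(self, t: int) -> Tuple[str, int]:
        """Read of read_length starting at transcript-oriented position t
        of the unspliced pre-mRNA (may run past the gene end)."""
        p = self.genomic_pos(t)
        L = self.read_length
        if self.model.strand == "+":
            return self.contig_seq[p : p + L], p
        return revcomp(self.contig_seq[p - L + 1 : p + 1]), p

    def mrna_read(self, t: int) -> Tuple[str, int, bool]:
        L = self.read_length
        seq = self.spliced[t : t + L]
        crosses = bool(self.exon_of[t] != self.exon_of[t + L - 1])
        return seq, int(self.splice_map[t]), crosses


def simulate_reads(
    sim: SimulatedGenome,
    config: Optional[SimulationConfig] = None,
    include_ncrnas: bool = True,
) -> List[SimulatedRead]:
    """Draw reads with the configured biases; deterministic given the seed.

    Genes are chosen proportionally to exp(expression).  With probability
    h the read starts at the transcript's first base (no hydrolysis
    needed); else with probability c it is drawn uniformly from the
    spliced mRNA; else uniformly from the unspliced pre-mRNA.  The
    first-base bias is applied by rejection sampling against the
    multiplier of the candidate read's first (as-sequenced) base.
    """
    config = config or sim.config
    rng = np.random.default_rng(config.seed + 1)
    pool_models = list(sim.models) + (list(sim.ncrnas) if include_ncrnas else [])
    pool = [
        _TranscriptIndex(m, sim.genome, config.read_length) for m in pool_models
    ]
    weights = np.exp([m.expression or 0.0 for m in pool_models])
    probs = weights / weights.sum()
    mult = config.multipliers()
    max_mult = max(mult.values())
    h = config.five_prime_enrichment
    c = config.mrna_fraction
    L = config.read_length
    reads: List[SimulatedRead] = []
    n = config.n_reads
    while len(reads) < n:
        nb = max(64, int((n - len(reads)) * (1.2 * max_mult)))
        gene_idx = rng.choice(len(pool), nb, p=probs)
        u_orig = rng.random((nb, 2))
        u_pos = rng.random(nb)
        u_acc = rng.random(nb)
        for j in range(nb):
            if len(reads) >= n:
                break
            ti = pool[gene_idx[j]]
            m = ti.model
            if u_orig[j, 0] < h:
                origin, t = "five_prime_start", 0
            elif u_orig[j, 1] < c:
                if len(ti.spliced) < L:
                    continue
                origin = "mRNA"
                t = int(u_pos[j] * (len(ti.spliced) - L + 1))
            else:
                origin = "pre_mRNA"
                t = int(u_pos[j] * ti.gene_len)
            if origin == "mRNA":
                seq, fp, crosses = ti.mrna_read(t)
            else:
                seq, fp = ti.pre_read(t)
                crosses = False
            first = seq[0]
            if u_acc[j] >= mult[first] / max_mult:
                continue  # rejected candidate; bias enters the data here
            error_cycle = -1
            if config.error_rate > 0 and rng.random() < config.error_rate:
                error_cycle = int(rng.integers(L))
                old = seq[error_cycle]
                new = BASES[(BASES.index(old) + 1 + int(rng.integers(3))) % 4]
                seq = seq[:error_cycle] + new + seq[error_cycle + 1 :]
            reads.append(
                SimulatedRead(
                    f"r{len(reads):07d}", seq, origin, m.id, m.contig,
                    m.strand, fp, t, crosses, error_cycle,
                )
            )
    return reads


def truth_table(reads: Sequence[SimulatedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "gene": [r.gene_id for r in reads],
            "origin": [r.origin for r in reads],
            "contig": [r.contig for r in reads],
            "strand": [r.strand for r in reads],
            "five_prime_genomic": [r.five_prime_genomic for r in reads],
            "transcript_pos": [r.transcript_pos for r in reads],
            "crosses_junction": [r.crosses_junction for r in reads],
            "error_cycle": [r.error_cycle for r in reads],
        }
    )


def write_fastq(reads: Iterable[SimulatedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def load_fastq(path: str) -> List[Tuple[str, str]]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header.strip().lstrip("@"), seq))
    return out


# ---------------------------------------------------------------------------
# Brute-force unique exact mapper (the alignment oracle)

ReadLike = Union[SimulatedRead, Tuple[str, str]]


def exact_unique_map(
    reads: Iterable[ReadLike], genome: Genome
) -> Tuple[List[MappedRead], Counter]:
    """Map reads that occur exactly once across both strands of the genome.

    A read is reported iff its sequence or its reverse complement matches
    exactly one genomic window (counting both possibilities together, so a
    palindromic repeat is non-unique).  The 5' anchor follows the shared
    convention: for minus-strand matches it is the highest covered
    coordinate.  align_score is the read length.
    """
    items = [
        (r.read_id, r.sequence) if isinstance(r, SimulatedRead) else tuple(r)
        for r in reads
    ]
    report: Counter = Counter()
    if not items:
        return [], report
    lengths = {len(seq) for _rid, seq in items}
    if len(lengths) != 1:
        raise ValueError("all reads must have the same length for exact mapping")
    L = lengths.pop()
    counts: Dict[str, int] = {}
    where: Dict[str, Tuple[str, int]] = {}
    for name, seq in genome.contigs.items():
        for i in range(len(seq) - L + 1):
            w = seq[i : i + L]
            cnt = counts.get(w, 0)
            counts[w] = cnt + 1
            if cnt == 0:
                where[w] = (name, i)
    mapped: List[MappedRead] = []
    for rid, seq in items:
        if "N" in seq:
            report["has_n"] += 1
            continue
        rc = revcomp(seq)
        occ = counts.get(seq, 0) + counts.get(rc, 0)
        if occ == 0:
            report["unmapped"] += 1
        elif occ > 1:
            report["non_unique"] += 1
        elif counts.get(seq, 0) == 1:
            contig, start = where[seq]
            mapped.append(
                MappedRead(rid, contig, "+", start, L, seq, 0, [], True, float(L))
            )
            report["mapped"] += 1
        else:
            contig, start = where[rc]
            mapped.append(
                MappedRead(
                    rid, contig, "-", start + L - 1, L, seq, 0, [], True, float(L)
                )
            )
            report["mapped"] += 1
    return mapped, report
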