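"""Leading k-mer inverse-frequency read weighting.

Each read is weighted by (1/4^k) / freq(kmer), where freq is the fraction
of the read pool beginning with that k-mer.  This statistically enforces a
uniform distribution of leading k-mers: the total weighted mass
contributed by reads starting with any observed k-mer is identical
(n_reads / 4^k), and when all 4^k k-mers are observed total mass equals
the number of reads.  With k=0 the track is the plain read-start pileup.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core_io import MappedRead


@dataclass
class KmerWeights:
    k: int
    freq: Dict[str, float]
    weight: Dict[str, float]
    n_reads: int = 0
    n_excluded: int = 0  # reads with N within the first k bases


@dataclass
class ScoreTrack:
    """Per-(contig, strand) sparse map of position -> read-start score."""

    data: Dict[Tuple[str, str], Dict[int, float]] = field(default_factory=dict)

    def add(self, contig: str, strand: str, pos: int, value: float) -> None:
        posmap = self.data.setdefault((contig, strand), {})
        posmap[pos] = posmap.get(pos, 0.0) + value

    def get(self, contig: str, strand: str, pos: int) -> float:
        return self.data.get((contig, strand), {}).get(pos, 0.0)

    def region_sum(self, contig: str, strand: str, start: int, end: int) -> float:
        posmap = self.data.get((contig, strand))
        if not posmap:
            return 0.0
        if end - start < len(posmap):
            return sum(posmap.get(p, 0.0) for p in range(start, end))
        return sum(v for p, v in posmap.items() if start <= p < end)

    def total(self) -> float:
        return sum(sum(m.values()) for m in self.data.values())


def estimate_kmer_weights(reads: Iterable[MappedRead], k: int) -> KmerWeights:
    """Estimate leading k-mer frequencies and inverse-frequency weights.

    Reads whose first k bases contain N are excluded from the pool (and
    counted); k=0 yields the single empty k-mer with weight 1.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    counts: Counter = Counter()
    n_excluded = 0
    n_reads = 0
    for read in reads:
        if read.length < k:
            raise ValueError(
                f"read {read.read_id!r} shorter than k={k}"
            )
        km = read.sequence[:k]
        if "N" in km:
            n_excluded += 1
            continue
        counts[km] += 1
        n_reads += 1
    if n_reads == 0:
        raise ValueError("empty read pool")
    uniform = 1.0 / (4 ** k)
    freq = {km: c / n_reads for km, c in counts.items()}
    weight = {km: uniform / f for km, f in freq.items()}
    return KmerWeights(k, freq, weight, n_reads, n_excluded)


def build_score_track(
    reads: Iterable[MappedRead], weights: KmerWeights
) -> Tuple[ScoreTrack, int]:
    """Allocate each read's weight to its 5'-anchor position.

    Reads whose leading k-mer is absent from ``weights`` (possible when
    weights come from a different pool) contribute nothing; their count is
    returned alongside the track.
    """
    track = ScoreTrack()
    n_unweighted = 0
    k = weights.k
    for read in reads:
        w = weights.weight.get(read.sequence[:k])
        if w is None:
            n_unweighted += 1
            continue
        track.add(read.contig, read.strand, read.five_prime_pos, w)
    return track, n_unweighted


# ---------------------------------------------------------------------------
# Splice-site peak fold-change

PEAK_SITES = ("acceptor_minus2", "donor_plus3")


@dataclass
class PeakFold:
    """Fold-change of a single-position splice-site peak over intronic
    background, for one expression bin."""

    site: str
    bin_label: str
    n_quintets: int
    peak_mean: float
    background_mean: float
    fold: Optional[float]
    fold_se: Optional[float]
    peak_values: np.ndarray = field(repr=False, default=None)
    background_values: np.ndarray = field(repr=False, default=None)
    excluded_small_bin: bool = False


def _site_positions(quintet, site: str) -> Tuple[int, List[int]]:
    """Genomic peak position and background positions for a quintet.

    Offsets follow transcript orientation: acceptor -2 is the 2nd intronic
    base upstream of the 3'ss (the consensus A of the AG); donor +3 is the
    3rd intronic base downstream of the 5'ss (the consensus A of GTA).
    Backgrounds are intronic offsets -200..-100 (upstream intron) and
    +100..+200 (downstream intron) respectively, clipped to the intron.
    """
    cs, ce = quintet.exon_central
    strand = quintet.strand
    if site == "acceptor_minus2":
        ilen = quintet.intron_up[1] - quintet.intron_up[0]
        offs = range(100, min(200, ilen) + 1)  # transcript offsets -100..-200
        if strand == "+":
            peak = cs - 2
            bg = [cs - o for o in offs]
        else:
            peak = ce + 1
            bg = [ce - 1 + o for o in offs]
    elif site == "donor_plus3":
        ilen = quintet.intron_down[1] - quintet.intron_down[0]
        offs = range(100, min(200, ilen) + 1)
        if strand == "+":
            peak = ce + 2
            bg = [ce - 1 + o for o in offs]
        else:
            peak = cs - 3
            bg = [cs - o for o in offs]
    else:
        raise ValueError(f"unknown site {site!r}; use one of {PEAK_SITES}")
    return peak, list(bg)


def peak_fold_change(
    track: ScoreTrack,
    quintets: Sequence,
    site: str,
    bin_index: Optional[Sequence[int]] = None,
    min_quintets: int = 10,
) -> List[PeakFold]:
    """Peak/background fold-change per expression bin.

    ``bin_index`` assigns each quintet to a bin (-1 = unbinned, dropped);
    with ``bin_index=None`` all quintets form a single bin.  Bins with
    fewer than ``min_quintets`` members are reported but flagged excluded.
    The SE of the fold is propagated from the SEMs of peak and background.
    """
    if bin_index is None:
        bin_index = [0] * len(quintets)
    results: List[PeakFold] = []
    for b in sorted(set(int(i) for i in bin_index if i >= 0)):
        members = [q for q, i in zip(quintets, bin_index) if int(i) == b]
        peaks = np.empty(len(members))
        bgs = np.empty(len(members))
        for j, q in enumerate(members):
            peak_pos, bg_pos = _site_positions(q, site)
            peaks[j] = track.get(q.contig, q.strand, peak_pos)
            bgs[j] = np.mean(
                [track.get(q.contig, q.strand, p) for p in bg_pos]
            )
        peak_mean = float(peaks.mean()) if len(members) else math.nan
        bg_mean = float(bgs.mean()) if len(members) else math.nan
        if bg_mean > 0:
            fold = peak_mean / bg_mean
            if len(members) >= 2:
                sem_p = peaks.std(ddof=1) / math.sqrt(len(members))
                sem_b = bgs.std(ddof=1) / math.sqrt(len(members))
                rel_p = sem_p / peak_mean if peak_mean > 0 else 0.0
                fold_se = fold * math.sqrt(rel_p ** 2 + (sem_b / bg_mean) ** 2)
            else:
                fold_se = None
        else:
            fold, fold_se = None, None  # undefined fold, flagged
        results.append(
            PeakFold(
                site, f"bin{b}", len(members), peak_mean, bg_mean, fold,
                fold_se, peaks, bgs, len(members) < min_quintets,
            )
        )
    return results


def pooled_fold(folds_a: PeakFold, folds_b: PeakFold) -> Tuple[float, float]:
    """Pool two single-position peaks measuring the same planted bias
    (acceptor -2 and donor +3): ratio of pooled peak and background means.
    Returns (fold, se)."""
    peaks = np.concatenate([folds_a.peak_values, folds_b.peak_values])
    bgs = np.concatenate([folds_a.background_values, folds_b.background_values])
    fold = peaks.mean() / bgs.mean()
    sem_p = peaks.std(ddof=1) / math.sqrt(len(peaks))
    sem_b = bgs.std(ddof=1) / math.sqrt(len(bgs))
    se = fold * math.sqrt((sem_p / peaks.mean()) ** 2 + (sem_b / bgs.mean()) ** 2)
    return float(fold), float(se)
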