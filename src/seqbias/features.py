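"""Exon-intron quintets, covariate binning, metagene profiles, and the
four-region Kruskal-Wallis test.

The quintet -- an internal exon, its two flanking introns and two flanking
internal exons -- is the unit of analysis for comparing read or
mappability densities between exons and introns.  Candidate quintets are
filtered so that every interval is at least ``min_len`` nt, the central
exon is at least ``boundary_gap`` from any annotated transcription start
or end site, no interval overlaps an RNA-gene record, and central-exon
coordinates are unique across the dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core_io import GeneModel, Interval
from .kmer_weighting import ScoreTrack
from .mappability import MappabilityTrack

NCRNA_BIOTYPES = {
    "CD_box_snoRNA", "HACA_box_snoRNA", "scaRNA", "miRNA", "tRNA", "rRNA",
    "other_ncRNA",
}


@dataclass
class ExonQuintet:
    transcript_id: str
    contig: str
    strand: str
    exon_up: Interval
    intron_up: Interval
    exon_central: Interval
    intron_down: Interval
    exon_down: Interval
    expression: Optional[float] = None

    def intervals(self) -> List[Interval]:
        return [
            self.exon_up, self.intron_up, self.exon_central,
            self.intron_down, self.exon_down,
        ]

    def validate(self, min_len: int = 32) -> None:
        ivs = self.intervals()
        if self.strand == "-":
            ivs = ivs[::-1]  # genomic order
        prev_end = None
        for s, e in ivs:
            if e - s < min_len:
                raise ValueError(f"{self.transcript_id}: interval shorter than {min_len}")
            if prev_end is not None and s != prev_end:
                raise ValueError(f"{self.transcript_id}: intervals not adjacent")
            prev_end = e


def _point_interval_gap(x: int, start: int, end: int) -> int:
    """Distance from point x to interval [start, end); 0 if inside."""
    if x < start:
        return start - x
    if x >= end:
        return x - (end - 1)
    return 0


def build_quintets(
    models: Sequence[GeneModel],
    rna_genes: Sequence[GeneModel] = (),
    min_len: int = 32,
    boundary_gap: int = 1000,
    strict_upstream: bool = False,
) -> Tuple[List[ExonQuintet], Dict[str, int]]:
    """Construct the quintet dataset with a per-filter attrition report.

    ``strict_upstream`` additionally requires the upstream exon to be at
    least ``boundary_gap`` from any transcription start site.
    """
    # transcript boundary sites per contig (both strands, edge coordinates)
    tss: Dict[str, List[int]] = {}
    tes: Dict[str, List[int]] = {}
    for m in models:
        tss.setdefault(m.contig, []).append(m.five_prime_end())
        tes.setdefault(m.contig, []).append(m.three_prime_end())
    sites = {
        c: np.array(sorted(tss.get(c, []) + tes.get(c, []))) for c in tss
    }
    tss_sorted = {c: np.array(sorted(v)) for c, v in tss.items()}

    rna_trees: Dict[str, IntervalTree] = {}
    for g in rna_genes:
        rna_trees.setdefault(g.contig, IntervalTree()).addi(g.tx_start, g.tx_end)

    def min_gap(contig: str, interval: Interval, positions: np.ndarray) -> int:
        s, e = interval
        if len(positions) == 0:
            return 1 << 30
        idx = np.searchsorted(positions, (s + e) // 2)
        best = 1 << 30
        for j in range(max(0, idx - 2), min(len(positions), idx + 3)):
            best = min(best, _point_interval_gap(int(positions[j]), s, e))
        return best

    report = {
        "candidates": 0, "fail_min_len": 0, "fail_boundary": 0,
        "fail_rna_overlap": 0, "fail_strict_upstream": 0,
        "fail_duplicate_central": 0, "kept": 0,
    }
    seen_centrals: set = set()
    quintets: List[ExonQuintet] = []
    for m in models:
        if m.biotype != "coding" or m.n_exons < 5:
            continue
        exons = m.exons  # genomic order
        introns = m.introns
        # candidate central exon index i (genomic): flanks must be internal
        for i in range(2, m.n_exons - 2):
            report["candidates"] += 1
            if m.strand == "+":
                parts = ExonQuintet(
                    m.id, m.contig, m.strand,
                    exons[i - 1], introns[i - 1], exons[i], introns[i], exons[i + 1],
                    m.expression,
                )
            else:
                parts = ExonQuintet(
                    m.id, m.contig, m.strand,
                    exons[i + 1], introns[i], exons[i], introns[i - 1], exons[i - 1],
                    m.expression,
                )
            if any(e - s < min_len for s, e in parts.intervals()):
                report["fail_min_len"] += 1
                continue
            if min_gap(m.contig, parts.exon_central, sites.get(m.contig, np.array([]))) < boundary_gap:
                report["fail_boundary"] += 1
                continue
            tree = rna_trees.get(m.contig)
            if tree is not None and any(
                tree.overlap(s, e) for s, e in parts.intervals()
            ):
                report["fail_rna_overlap"] += 1
                continue
            if strict_upstream and min_gap(
                m.contig, parts.exon_up, tss_sorted.get(m.contig, np.array([]))
            ) < boundary_gap:
                report["fail_strict_upstream"] += 1
                continue
            key = (m.contig, parts.exon_central)
            if key in seen_centrals:
                report["fail_duplicate_central"] += 1
                continue
            seen_centrals.add(key)
            quintets.append(parts)
            report["kept"] += 1
    return quintets, report


def dedup_isoforms(
    models: Sequence[GeneModel],
    clusters: Mapping[str, str],
    seed: int = 0,
) -> List[GeneModel]:
    """Keep one randomly selected isoform per cluster (seeded RNG).

    Models absent from ``clusters`` form singleton clusters.
    """
    rng = np.random.default_rng(seed)
    by_cluster: Dict[str, List[GeneModel]] = {}
    for m in models:
        by_cluster.setdefault(clusters.get(m.id, m.id), []).append(m)
    kept = []
    for cluster_id in sorted(by_cluster):
        group = by_cluster[cluster_id]
        kept.append(group[int(rng.integers(len(group)))])
    kept.sort(key=lambda m: (m.contig, m.tx_start, m.id))
    return kept


# ---------------------------------------------------------------------------
# Binning


def assign_bins(
    values: Sequence[Optional[float]], n_bins: int
) -> Tuple[np.ndarray, int]:
    """Quantile bins of (as near as possible) equal size, ordered by value.

    Returns (bin index per feature, number dropped).  Features with value
    None get bin -1 (dropped).  Ties are resolved by stable input order, so
    identical values split into near-equal groups deterministically.
    """
    vals = np.array([np.nan if v is None else float(v) for v in values])
    defined = np.flatnonzero(~np.isnan(vals))
    n_dropped = len(vals) - len(defined)
    if n_bins > len(defined):
        raise ValueError(f"n_bins={n_bins} > {len(defined)} features with values")
    order = defined[np.argsort(vals[defined], kind="stable")]
    bins = np.full(len(vals), -1, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins, n_dropped


# ---------------------------------------------------------------------------
# Metagene profiles

Anchor = Tuple[str, str, int]  # (contig, strand, genomic position of offset 0)

Track = Union[ScoreTrack, MappabilityTrack]


@dataclass
class MetageneProfile:
    """Mean signal per offset across features aligned at a common anchor.

    Offsets follow transcript orientation (negative = upstream).  When a
    mappability mask is supplied, unmappable positions are excluded from
    both the numerator and the per-offset denominator ``n_contributing``.
    SEM is defined only where n_contributing >= 2.
    """

    anchor: str
    offsets: np.ndarray
    mean_density: np.ndarray
    sem: np.ndarray
    n_contributing: np.ndarray
    bin_label: str = "all"


def _track_value(track: Track, contig: str, strand: str, pos: int) -> float:
    if isinstance(track, MappabilityTrack):
        return float(track.data[(contig, strand)][pos])
    return track.get(contig, strand, pos)


def _contig_length(track: Track, contig: str) -> Optional[int]:
    if isinstance(track, MappabilityTrack):
        return track.contig_length(contig)
    return None


def metagene_profile(
    anchors: Sequence[Anchor],
    track: Track,
    flank: int,
    mappability: Optional[MappabilityTrack] = None,
    anchor_label: str = "anchor",
    bin_label: str = "all",
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> MetageneProfile:
    """Per-offset mean of ``track`` over features aligned at their anchor.

    Offsets run -flank..+flank; minus-strand features are flipped so that
    positive offsets point downstream in transcript orientation.  Features
    whose flank extends beyond the contig contribute only defined offsets.
    """
    offsets = np.arange(-flank, flank + 1)
    n_off = len(offsets)
    total = np.zeros(n_off)
    total_sq = np.zeros(n_off)
    n = np.zeros(n_off, dtype=int)
    for contig, strand, pos in anchors:
        if contig_lengths is not None:
            clen = contig_lengths[contig]
        else:
            clen = _contig_length(mappability if mappability is not None else track, contig)
        sign = 1 if strand == "+" else -1
        gpos = pos + sign * offsets
        ok = gpos >= 0
        if clen is not None:
            ok &= gpos < clen
        for j in np.flatnonzero(ok):
            p = int(gpos[j])
            if mappability is not None and not mappability.data[(contig, strand)][p]:
                continue
            v = _track_value(track, contig, strand, p)
            total[j] += v
            total_sq[j] += v * v
            n[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
        var = np.where(
            n >= 2,
            (total_sq - np.maximum(n, 1) * mean ** 2) / np.maximum(n - 1, 1),
            np.nan,
        )
        sem = np.sqrt(np.maximum(var, 0.0) / np.maximum(n, 1))
    sem[n < 2] = np.nan
    return MetageneProfile(anchor_label, offsets, mean, sem, n, bin_label)


def anchors_3ss(quintets: Sequence[ExonQuintet]) -> List[Anchor]:
    """Offset 0 = first base of the central exon (transcript orientation)."""
    out = []
    for q in quintets:
        cs, ce = q.exon_central
        out.append((q.contig, q.strand, cs if q.strand == "+" else ce - 1))
    return out


def anchors_5ss(quintets: Sequence[ExonQuintet]) -> List[Anchor]:
    """Offset 0 = last base of the central exon (transcript orientation)."""
    out = []
    for q in quintets:
        cs, ce = q.exon_central
        out.append((q.contig, q.strand, ce - 1 if q.strand == "+" else cs))
    return out


def anchors_start(models: Sequence[GeneModel]) -> List[Anchor]:
    return [(m.contig, m.strand, m.five_prime_end()) for m in models]


def anchors_end(models: Sequence[GeneModel]) -> List[Anchor]:
    return [(m.contig, m.strand, m.three_prime_end()) for m in models]


# ---------------------------------------------------------------------------
# Four-region Kruskal-Wallis test

REGIONS = (
    "upstream_intron_200", "exon_first_100", "exon_last_100",
    "downstream_intron_200",
)


def _region_interval(q: ExonQuintet, region: str) -> Interval:
    """Genomic interval of a named region, in transcript orientation,
    clipped to the available feature length."""
    cs, ce = q.exon_central
    elen = ce - cs
    iu_len = q.intron_up[1] - q.intron_up[0]
    id_len = q.intron_down[1] - q.intron_down[0]
    plus = q.strand == "+"
    if region == "upstream_intron_200":
        w = min(200, iu_len)
        return (cs - w, cs) if plus else (ce, ce + w)
    if region == "exon_first_100":
        w = min(100, elen)
        return (cs, cs + w) if plus else (ce - w, ce)
    if region == "exon_last_100":
        w = min(100, elen)
        return (ce - w, ce) if plus else (cs, cs + w)
    if region == "downstream_intron_200":
        w = min(200, id_len)
        return (ce, ce + w) if plus else (cs - w, cs)
    raise ValueError(f"unknown region {region!r}")


def _region_mean(q: ExonQuintet, region: str, track: Track) -> float:
    s, e = _region_interval(q, region)
    if isinstance(track, MappabilityTrack):
        return float(track.data[(q.contig, q.strand)][s:e].mean())
    return track.region_sum(q.contig, q.strand, s, e) / (e - s)


@dataclass
class KruskalWallisResult:
    per_region: Dict[str, Tuple[float, float]]  # region -> (H, p)
    summary_p: float  # the maximum (least significant) of the region p's
    n_groups: int


def kruskal_wallis_region_test(
    quintets: Sequence[ExonQuintet],
    bin_index: Sequence[int],
    track: Track,
) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis rank test of per-quintet region means
    across bins, for each of the four regions around the central exon; the
    summary p is the maximum (least significant) over regions."""
    groups_idx: Dict[int, List[int]] = {}
    for j, b in enumerate(bin_index):
        if b >= 0:
            groups_idx.setdefault(int(b), []).append(j)
    usable = {}
    for b, idx in sorted(groups_idx.items()):
        if len(idx) < 2:
            warnings.warn(f"bin {b} has <2 members; excluded from the test")
            continue
        usable[b] = idx
    if len(usable) < 2:
        raise ValueError("need at least 2 non-empty groups")
    per_region: Dict[str, Tuple[float, float]] = {}
    for region in REGIONS:
        samples = []
        for b, idx in usable.items():
            samples.append([_region_mean(quintets[j], region, track) for j in idx])
        h, p = stats.kruskal(*samples)
        per_region[region] = (float(h), float(p))
    summary_p = max(p for _h, p in per_region.values())
    return KruskalWallisResult(per_region, summary_p, len(usable))


# ---------------------------------------------------------------------------
# Windowed region means (e.g. conservation over terminal intronic nt)


def mean_region_score(
    scores: Mapping[int, float],
    region: Interval,
    window: str = "all",
    exon_side: Optional[str] = None,
    terminal_len: int = 50,
) -> Optional[float]:
    """Mean of per-position scores over a region or its terminal window.

    ``window='terminal_50'`` selects the ``terminal_len`` positions of the
    region adjacent to the exon, whose genomic side is ``exon_side``
    ('left' = exon precedes the region, so the window hugs the region
    start; 'right' = the window hugs the region end).  Positions missing
    from ``scores`` are absent from both numerator and denominator; an
    all-missing window returns None.
    """
    start, end = region
    if window == "terminal_50":
        if exon_side not in ("left", "right"):
            raise ValueError("terminal window needs exon_side 'left' or 'right'")
        if end - start < terminal_len:
            raise ValueError("region shorter than the terminal window")
        if exon_side == "left":
            start, end = start, start + terminal_len
        else:
            start, end = end - terminal_len, end
    elif window != "all":
        raise ValueError(f"unknown window {window!r}")
    vals = [scores[p] for p in range(start, end) if p in scores]
    if not vals:
        return None
    return float(np.mean(vals))
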