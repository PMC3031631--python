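"""Per-strand mappability tracks and mappability-normalized densities.

A plus-strand position p is mappable iff the read_length window starting
at p occurs exactly once among all windows of both genome strands; a
minus-strand position p is assessed on the reverse complement of the
window ending at p (the window a minus-strand read anchored at p would
produce).  Windows containing N are unmappable, as is a window equal to
its own reverse complement (it occurs on both strands of one locus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from ._util import encode
from .core_io import Genome
from .kmer_weighting import ScoreTrack


class CapacityError(RuntimeError):
    """Genome too large for the brute-force mismatch-tolerant mode."""


@dataclass
class MappabilityTrack:
    read_length: int
    data: Dict[Tuple[str, str], np.ndarray]  # (contig, strand) -> bool vector

    def is_mappable(self, contig: str, strand: str, pos: int) -> bool:
        return bool(self.data[(contig, strand)][pos])

    def contig_length(self, contig: str) -> int:
        return len(self.data[(contig, "+")])


def _window_codes(codes: np.ndarray, L: int) -> Tuple[np.ndarray, np.ndarray]:
    """(windows as (n-L+1, L) uint8 view, validity mask: no N in window)."""
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    has_n = np.convolve((codes == 4).astype(np.int32), np.ones(L, dtype=np.int32))
    valid = has_n[L - 1 : len(codes)] == 0
    return win, valid


def _void_view(win: np.ndarray) -> np.ndarray:
    """View each L-byte window row as a single opaque item for counting."""
    w = np.ascontiguousarray(win)
    return w.view([("w", f"V{w.shape[1]}")])["w"].reshape(-1)


def build_mappability_track(
    genome: Genome,
    read_length: int,
    max_mismatches: int = 0,
    mismatch_genome_cap: int = 20_000,
) -> MappabilityTrack:
    """Exhaustively enumerate all read_length windows of both strands and
    mark positions whose window occurs exactly once genome-wide.

    ``max_mismatches`` in {1, 2} switches to a brute-force all-pairs
    Hamming comparison where any second window within the distance destroys
    uniqueness; this mode is limited to genomes of total length at most
    ``mismatch_genome_cap``.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1, or 2")
    if max_mismatches > 0:
        total = sum(len(s) for s in genome.contigs.values())
        if total > mismatch_genome_cap:
            raise CapacityError(
                f"genome ({total} nt) exceeds the {mismatch_genome_cap} nt cap "
                "for mismatch-tolerant mappability"
            )
        return _build_hamming(genome, read_length, max_mismatches)
    return _build_exact(genome, read_length)


def _build_exact(genome: Genome, L: int) -> MappabilityTrack:
    # collect valid windows of both strands into one array, remembering the
    # anchor slot of each so singleton flags can be scattered back
    chunks = []
    slots = []  # (contig, strand, anchor indices aligned with the chunk)
    for name, seq in genome.contigs.items():
        codes = encode(seq)
        rc_codes = (3 - codes[::-1]) % 8  # A<->T, C<->G; N (4) -> 7, reset below
        rc_codes[codes[::-1] == 4] = 4
        n = len(seq)
        if n < L:
            continue
        win_p, valid_p = _window_codes(codes, L)
        win_m, valid_m = _window_codes(rc_codes, L)
        idx_p = np.flatnonzero(valid_p)
        idx_m = np.flatnonzero(valid_m)
        chunks.append(_void_view(win_p)[idx_p])
        slots.append((name, "+", idx_p))
        # rc window starting at i (in reversed coords) anchors minus-strand
        # position n-1-i
        chunks.append(_void_view(win_m)[idx_m])
        slots.append((name, "-", n - 1 - idx_m))
    if not chunks:
        raise ValueError("no contig is as long as read_length")
    allwin = np.concatenate(chunks)
    _uniq, inverse, counts = np.unique(
        allwin, return_inverse=True, return_counts=True
    )
    single = counts[inverse] == 1

    data: Dict[Tuple[str, str], np.ndarray] = {}
    for name, seq in genome.contigs.items():
        data[(name, "+")] = np.zeros(len(seq), dtype=bool)
        data[(name, "-")] = np.zeros(len(seq), dtype=bool)
    offset = 0
    for chunk, (name, strand, anchors) in zip(chunks, slots):
        flags = single[offset : offset + len(chunk)]
        data[(name, strand)][anchors[flags]] = True
        offset += len(chunk)
    return MappabilityTrack(L, data)


def _build_hamming(genome: Genome, L: int, mm: int) -> MappabilityTrack:
    wins = []
    anchors = []  # (contig, strand, anchor position)
    for name, seq in genome.contigs.items():
        codes = encode(seq)
        n = len(seq)
        if n < L:
            continue
        win_p, valid_p = _window_codes(codes, L)
        for i in np.flatnonzero(valid_p):
            wins.append(win_p[i])
            anchors.append((name, "+", int(i)))
        rc_codes = (3 - codes[::-1]) % 8
        rc_codes[codes[::-1] == 4] = 4
        win_m, valid_m = _window_codes(rc_codes, L)
        for i in np.flatnonzero(valid_m):
            wins.append(win_m[i])
            anchors.append((name, "-", int(n - 1 - i)))
    if not wins:
        raise ValueError("no contig is as long as read_length")
    W = np.array(wins, dtype=np.uint8)
    M = len(W)
    unique_flags = np.ones(M, dtype=bool)
    chunk = max(1, 2_000_000 // max(M, 1))
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        # Hamming distance of every window in the chunk to every window
        d = (W[lo:hi, None, :] != W[None, :, :]).sum(axis=2)
        near = (d <= mm).sum(axis=1)  # includes self (distance 0)
        unique_flags[lo:hi] = near == 1
    data: Dict[Tuple[str, str], np.ndarray] = {}
    for name, seq in genome.contigs.items():
        data[(name, "+")] = np.zeros(len(seq), dtype=bool)
        data[(name, "-")] = np.zeros(len(seq), dtype=bool)
    for flag, (name, strand, pos) in zip(unique_flags, anchors):
        if flag:
            data[(name, strand)][pos] = True
    return MappabilityTrack(L, data)


# ---------------------------------------------------------------------------
# Densities


def mappability_density(
    track: MappabilityTrack, contig: str, strand: str, start: int, end: int
) -> float:
    """Fraction of mappable positions within [start, end)."""
    if end <= start:
        raise ValueError("empty region")
    vec = track.data[(contig, strand)]
    if start < 0 or end > len(vec):
        raise ValueError(f"region [{start},{end}) outside contig {contig!r}")
    return float(vec[start:end].mean())


@dataclass
class RegionDensity:
    """Mappability-normalized read density: sum of scores over the region
    divided by the number of mappable positions.  ``defined`` is False when
    the region has no mappable positions (never a silent zero)."""

    score_sum: float
    n_mappable: int
    length: int

    @property
    def defined(self) -> bool:
        return self.n_mappable > 0

    @property
    def density(self) -> Optional[float]:
        if not self.defined:
            return None
        return self.score_sum / self.n_mappable


def region_read_density(
    track: MappabilityTrack,
    score_track: ScoreTrack,
    contig: str,
    strand: str,
    start: int,
    end: int,
) -> RegionDensity:
    vec = track.data[(contig, strand)]
    if start < 0 or end > len(vec):
        raise ValueError(f"region [{start},{end}) outside contig {contig!r}")
    n_mappable = int(vec[start:end].sum())
    posmap = score_track.data.get((contig, strand), {})
    score = 0.0
    if posmap:
        if end - start < len(posmap):
            score = sum(
                posmap.get(p, 0.0) for p in range(start, end) if vec[p]
            )
        else:
            score = sum(v for p, v in posmap.items() if start <= p < end and vec[p])
    return RegionDensity(score, n_mappable, end - start)
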