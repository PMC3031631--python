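"""Exon-exon junction libraries, junction-read selection and projection,
and the analytic mRNA-contamination model.

Reads sequenced from spliced mRNA that straddle an exon-exon boundary
cannot align to the genome; they are recovered by aligning against a
library of 62-nt junction sequences (last 31 nt of the donor exon + first
31 nt of the acceptor exon) and projecting accepted reads back to genomic
coordinates through each junction's coordinate map.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._util import revcomp
from .core_io import Genome, Interval, MappedRead
from .features import ExonQuintet, assign_bins
from .kmer_weighting import ScoreTrack
from .mappability import MappabilityTrack, region_read_density

JUNCTION_FLANK = 31
JUNCTION_LENGTH = 2 * JUNCTION_FLANK
PAIRS = ("up_central", "central_down")


@dataclass
class JunctionRecord:
    junction_id: str
    pair: str
    transcript_id: str
    contig: str
    strand: str
    donor_exon: Interval
    acceptor_exon: Interval
    sequence: str
    coord_map: np.ndarray  # junction-local offset (0..61) -> genomic position

    def __post_init__(self) -> None:
        assert len(self.sequence) == JUNCTION_LENGTH
        assert len(self.coord_map) == JUNCTION_LENGTH


def build_junction_library(
    quintets: Sequence[ExonQuintet], genome: Genome, pair: str
) -> List[JunctionRecord]:
    """One 62-nt junction record per quintet for the requested exon pair
    (upstream|central or central|downstream), in transcript orientation."""
    if pair not in PAIRS:
        raise ValueError(f"pair must be one of {PAIRS}")
    records = []
    for q in quintets:
        donor = q.exon_up if pair == "up_central" else q.exon_central
        acceptor = q.exon_central if pair == "up_central" else q.exon_down
        ds, de = donor
        as_, ae = acceptor
        if q.strand == "+":
            seq = genome.contigs[q.contig][de - JUNCTION_FLANK : de]
            seq += genome.contigs[q.contig][as_ : as_ + JUNCTION_FLANK]
            coords = np.concatenate(
                [np.arange(de - JUNCTION_FLANK, de), np.arange(as_, as_ + JUNCTION_FLANK)]
            )
        else:
            # transcript-orientation last 31 nt of the donor are the genomic
            # first 31 nt of its interval, reverse complemented
            seq = revcomp(genome.contigs[q.contig][ds : ds + JUNCTION_FLANK])
            seq += revcomp(genome.contigs[q.contig][ae - JUNCTION_FLANK : ae])
            coords = np.concatenate(
                [
                    np.arange(ds + JUNCTION_FLANK - 1, ds - 1, -1),
                    np.arange(ae - 1, ae - JUNCTION_FLANK - 1, -1),
                ]
            )
        jid = (
            f"{q.transcript_id}|{pair}|{q.contig}:"
            f"{q.exon_central[0]}-{q.exon_central[1]}({q.strand})"
        )
        records.append(
            JunctionRecord(
                jid, pair, q.transcript_id, q.contig, q.strand,
                donor, acceptor, seq, coords,
            )
        )
    return records


def junction_genome(records: Sequence[JunctionRecord]) -> Genome:
    """The junction library as a pseudo-genome (one contig per junction),
    suitable for any aligner; exported to FASTA via core_io.write_genome."""
    return Genome({r.junction_id: r.sequence for r in records})


def write_junction_fasta(records: Sequence[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.junction_id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# Selection and projection


def select_junction_reads(
    junction_hits: Iterable[MappedRead],
    genome_hits: Mapping[str, MappedRead],
    min_overlap: int = 4,
) -> Tuple[List[MappedRead], Counter]:
    """Filter junction-library alignments.

    A hit is accepted iff it covers at least ``min_overlap`` nt on each
    side of the exon-exon boundary (offsets 30|31) and either has no
    genomic alignment or scores strictly higher on the junction than on
    the genome (equal scores are rejected, the conservative reading).
    Junction hits must be unique within the library and on the sense
    strand of the junction sequence.
    """
    accepted: List[MappedRead] = []
    reasons: Counter = Counter()
    for hit in junction_hits:
        if not hit.unique:
            reasons["not_unique"] += 1
            continue
        if hit.strand != "+":
            reasons["antisense"] += 1
            continue
        start = hit.five_prime_pos  # junction-local offset of the 5' base
        left = JUNCTION_FLANK - start
        right = start + hit.length - JUNCTION_FLANK
        if left < min_overlap or right < min_overlap:
            reasons["overlap"] += 1
            continue
        genomic = genome_hits.get(hit.read_id)
        if genomic is not None and not hit.align_score > genomic.align_score:
            reasons["genome_scores_not_lower"] += 1
            continue
        accepted.append(hit)
        reasons["accepted"] += 1
    return accepted, reasons


def project_junction_reads(
    accepted: Iterable[MappedRead],
    records: Mapping[str, JunctionRecord],
) -> List[MappedRead]:
    """Map accepted junction reads back to genomic coordinates: the
    genomic 5'-anchor is the coordinate-map entry of the junction-local 5'
    offset.  Projected reads enter the score pipeline like genomic reads."""
    projected = []
    for hit in accepted:
        rec = records[hit.contig]
        offset = hit.five_prime_pos
        if not 0 <= offset < JUNCTION_LENGTH:
            raise RuntimeError(f"junction-local offset {offset} outside 0..61")
        projected.append(
            MappedRead(
                hit.read_id, rec.contig, rec.strand, int(rec.coord_map[offset]),
                hit.length, hit.sequence, hit.n_mismatches,
                list(hit.mismatch_positions), True, hit.align_score,
            )
        )
    return projected


# ---------------------------------------------------------------------------
# Contamination quantification


def junction_coverage_by_bin(
    quintets: Sequence[ExonQuintet],
    accepted: Iterable[MappedRead],
    records: Sequence[JunctionRecord],
    n_bins: int = 200,
) -> pd.DataFrame:
    """Fraction of exons with at least one junction read, per expression
    bin of gradually increasing expression."""
    # records are built per quintet in order
    jid_to_idx = {r.junction_id: i for i, r in enumerate(records)}
    covered = np.zeros(len(quintets), dtype=bool)
    for hit in accepted:
        idx = jid_to_idx.get(hit.contig)
        if idx is not None:
            covered[idx] = True
    bins, _ = assign_bins([q.expression for q in quintets], n_bins)
    rows = []
    for b in range(n_bins):
        members = bins == b
        n = int(members.sum())
        frac = float(covered[members].mean()) if n else float("nan")
        rows.append({"bin": b, "n_exons": n, "fraction_with_junction_reads": frac})
    return pd.DataFrame(rows)


@dataclass
class ContaminationEstimate:
    """Exon vs flanking-intron density excess, per expression bin.

    ``pct_excess`` = 100 * (exon density / mean flanking-intron density - 1),
    defined only where both intron densities are positive.  P-values are
    two-sided two-sample Student's t-tests of per-quintet densities.
    """

    per_bin: pd.DataFrame
    exon_density: float
    intron_up_density: float
    intron_down_density: float
    pct_excess: Optional[float]


def _quintet_densities(
    q: ExonQuintet, track: ScoreTrack, mapp: MappabilityTrack
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    out = []
    for s, e in (q.exon_central, q.intron_up, q.intron_down):
        d = region_read_density(mapp, track, q.contig, q.strand, s, e)
        out.append(d.density)
    return tuple(out)


def estimate_contamination(
    quintets: Sequence[ExonQuintet],
    score_track: ScoreTrack,
    mappability: MappabilityTrack,
    n_bins: int = 5,
) -> ContaminationEstimate:
    """Mappability-normalized read-density excess of central exons over
    their flanking introns, overall and per expression bin."""
    dens = np.array(
        [_quintet_densities(q, score_track, mappability) for q in quintets],
        dtype=float,
    )
    bins, _ = assign_bins([q.expression for q in quintets], n_bins)
    rows = []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        rows.append(_excess_row(f"bin{b}", dens[members]))
    per_bin = pd.DataFrame(rows)
    overall = _excess_row("all", dens)
    return ContaminationEstimate(
        per_bin,
        overall["exon_density"],
        overall["intron_up_density"],
        overall["intron_down_density"],
        overall["pct_excess"],
    )


def _excess_row(label: str, dens: np.ndarray) -> dict:
    ok = ~np.isnan(dens).any(axis=1)
    d = dens[ok]
    row = {
        "bin": label, "n_quintets": int(ok.sum()),
        "exon_density": np.nan, "intron_up_density": np.nan,
        "intron_down_density": np.nan, "pct_excess": np.nan,
        "p_vs_intron_up": np.nan, "p_vs_intron_down": np.nan,
        "flagged": False,
    }
    if len(d) == 0:
        row["flagged"] = True
        return row
    exon, up, down = d.mean(axis=0)
    row.update(exon_density=exon, intron_up_density=up, intron_down_density=down)
    if up > 0 and down > 0:
        row["pct_excess"] = 100.0 * (exon / ((up + down) / 2.0) - 1.0)
    else:
        row["flagged"] = True
    if len(d) >= 2:
        row["p_vs_intron_up"] = float(stats.ttest_ind(d[:, 0], d[:, 1]).pvalue)
        row["p_vs_intron_down"] = float(stats.ttest_ind(d[:, 0], d[:, 2]).pvalue)
    return row


# ---------------------------------------------------------------------------
# Analytic contamination model


@dataclass
class ContaminationPrediction:
    exonic_before: float
    intronic_before: float
    exonic_after: float
    pct_density_increase: float


def predict_contamination_effect(
    total_reads: float, intron_to_exon_length_ratio: float, contaminating_reads: float
) -> ContaminationPrediction:
    """Closed-form contamination model: reads generated uniformly over a
    pre-mRNA whose introns are r-fold longer than its exons, plus C
    contaminating mRNA reads that land exclusively in exons.

    Intronic coverage is essentially unchanged by the contaminants, so the
    exonic density increase is 100 * C / exonic_before percent.
    """
    r = intron_to_exon_length_ratio
    if r <= 0:
        raise ValueError("intron_to_exon_length_ratio must be > 0")
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if contaminating_reads < 0:
        raise ValueError("contaminating_reads must be >= 0")
    exonic_before = total_reads / (1.0 + r)
    intronic_before = total_reads * r / (1.0 + r)
    exonic_after = exonic_before + contaminating_reads
    pct = 100.0 * contaminating_reads / exonic_before
    return ContaminationPrediction(exonic_before, intronic_before, exonic_after, pct)
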