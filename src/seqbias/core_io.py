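"""Readers, writers, and the shared in-memory data model.

All internal coordinates are 0-based half-open; conversions to and from
1-based formats (GTF, SAM) happen only at file boundaries.  A read is
anchored at its 5'-most genomic coordinate, which for a minus-strand read
is the *highest* genomic position it covers.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import clean_sequence, revcomp

BIOTYPES = {
    "coding",
    "CD_box_snoRNA",
    "HACA_box_snoRNA",
    "scaRNA",
    "miRNA",
    "tRNA",
    "rRNA",
    "other_ncRNA",
}

Interval = Tuple[int, int]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class Genome:
    """Named DNA sequences over {A,C,G,T,N}, uppercase."""

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise FormatError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not name:
                raise FormatError("empty contig name")
            if not seq:
                raise FormatError(f"contig {name!r} has empty sequence")

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-aware subsequence; minus strand returns the reverse
        complement of the plus-strand interval [start, end)."""
        seq = self.contigs[contig][start:end]
        return revcomp(seq) if strand == "-" else seq


@dataclass
class GeneModel:
    """A stranded transcript with exon blocks.

    ``exons`` are 0-based half-open genomic intervals sorted by genomic
    start regardless of strand; ``expression`` is in arbitrary log units.
    """

    id: str
    contig: str
    strand: str
    tx_start: int
    tx_end: int
    exons: List[Interval]
    biotype: str = "coding"
    expression: Optional[float] = None

    def validate(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.id}: bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise FormatError(f"{self.id}: tx_start must be < tx_end")
        if not self.exons:
            raise FormatError(f"{self.id}: no exons")
        if self.biotype not in BIOTYPES:
            raise FormatError(f"{self.id}: unknown biotype {self.biotype!r}")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise FormatError(
                    f"{self.id}: exon ({s},{e}) outside transcript "
                    f"[{self.tx_start},{self.tx_end})"
                )
            if prev_end is not None and s < prev_end:
                raise FormatError(f"{self.id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def introns(self) -> List[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: Genome) -> str:
        parts = [genome.contigs[self.contig][s:e] for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def five_prime_end(self) -> int:
        """Genomic coordinate of the transcript's first (5') base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def three_prime_end(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


@dataclass
class MappedRead:
    """A mapped read anchored at its 5'-most genomic coordinate.

    ``mismatch_positions`` are 0-based read-cycle indices (as sequenced);
    ``align_score`` is canonicalized so higher = better.
    """

    read_id: str
    contig: str
    strand: str
    five_prime_pos: int
    length: int
    sequence: str
    n_mismatches: int = 0
    mismatch_positions: List[int] = field(default_factory=list)
    unique: bool = True
    align_score: float = 0.0

    def covered_interval(self) -> Interval:
        """Genomic interval [start, end) covered by the read."""
        if self.strand == "+":
            return (self.five_prime_pos, self.five_prime_pos + self.length)
        return (self.five_prime_pos - self.length + 1, self.five_prime_pos + 1)


# ---------------------------------------------------------------------------
# FASTA


def load_genome(path: str) -> Genome:
    """Load a FASTA file; bases are uppercased, non-ACGTN mapped to N."""
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig name {rec.id!r}")
        contigs[rec.id] = clean_sequence(str(rec.seq))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_genome(genome: Genome, path: str, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython wraps at 60 by default


# ---------------------------------------------------------------------------
# Annotation (BED12 / GTF)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')

_BIOTYPE_ALIASES = {
    "protein_coding": "coding",
    "coding": "coding",
    "snoRNA_CD": "CD_box_snoRNA",
    "snoRNA_HACA": "HACA_box_snoRNA",
}


def _normalize_biotype(raw: str) -> str:
    if raw in BIOTYPES:
        return raw
    return _BIOTYPE_ALIASES.get(raw, "other_ncRNA")


def load_annotation(path: str, default_biotype: str = "coding") -> List[GeneModel]:
    """Load gene models from BED12 or GTF (chosen by file extension)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".bed", ".bed12"):
        models = _load_bed12(path, default_biotype)
    elif ext in (".gtf", ".gff"):
        models = _load_gtf(path, default_biotype)
    else:
        raise FormatError(f"cannot infer annotation format from {path!r}")
    for m in models:
        m.validate()
    return models


def _load_bed12(path: str, default_biotype: str) -> List[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            models.append(
                GeneModel(name, chrom, strand, start, end, exons, default_biotype)
            )
    return models


def _load_gtf(path: str, default_biotype: str) -> List[GeneModel]:
    exons: Dict[str, List[Interval]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (contig, strand, biotype)
    bounds: Dict[str, Interval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
            contig, _src, feature, start1, end1, _score, strand, _frame, attrs = f[:9]
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id")
            if tid is None:
                continue
            start, end = int(start1) - 1, int(end1)  # 1-based inclusive -> half-open
            biotype = _normalize_biotype(
                attr.get("transcript_biotype", attr.get("gene_biotype", default_biotype))
            )
            if feature == "transcript":
                bounds[tid] = (start, end)
                meta.setdefault(tid, (contig, strand, biotype))
            elif feature == "exon":
                exons.setdefault(tid, []).append((start, end))
                meta.setdefault(tid, (contig, strand, biotype))
    models = []
    for tid, exs in exons.items():
        contig, strand, biotype = meta[tid]
        exs = sorted(exs)
        tx_start, tx_end = bounds.get(tid, (exs[0][0], exs[-1][1]))
        for s, e in exs:
            if not (tx_start <= s < e <= tx_end):
                raise FormatError(
                    f"transcript {tid!r}: exon ({s},{e}) outside bounds"
                )
        models.append(GeneModel(tid, contig, strand, tx_start, tx_end, exs, biotype))
    models.sort(key=lambda m: (m.contig, m.tx_start, m.id))
    return models


def write_bed12(models: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - m.tx_start) for s, e in m.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.contig, m.tx_start, m.tx_end, m.id, 0, m.strand,
                        m.tx_start, m.tx_end, "0,0,0", len(m.exons), sizes, starts,
                    )
                )
                + "\n"
            )


def write_gtf(models: Sequence[GeneModel], path: str, source: str = "seqbias") -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'transcript_id "{m.id}"; transcript_biotype "{m.biotype}";'
            fh.write(
                f"{m.contig}\t{source}\ttranscript\t{m.tx_start + 1}\t{m.tx_end}\t."
                f"\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def load_expression(path: str) -> Dict[str, float]:
    """Two-column TSV (id, log expression); a non-numeric first row is a header."""
    table: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, value = line.split("\t")[:2]
            try:
                table[name] = float(value)
            except ValueError:
                if table:
                    raise FormatError(f"bad expression value {value!r}")
                # header row
    return table


def write_expression(table: Mapping[str, float], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tlog_expression\n")
        for name, value in table.items():
            fh.write(f"{name}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# Alignments (SAM/BAM and a minimal TSV dialect)

TSV_COLUMNS = [
    "read_id", "contig", "strand", "five_prime_pos", "length", "sequence",
    "n_mismatches", "mismatch_positions", "unique", "align_score",
]


def load_alignments(
    path: str,
    genome: Optional[Genome] = None,
    unique_mapq: Optional[int] = 1,
    unique_tag: Optional[str] = None,
    score_tag: str = "AS",
    score_sense: str = "higher",
) -> Tuple[List[MappedRead], Dict[str, int]]:
    """Load mapped reads from SAM/BAM or the minimal TSV dialect.

    Uniqueness is mapper-specific: it is read from ``unique_tag`` (e.g. NH,
    value 1 = unique) when given, else from ``mapq >= unique_mapq``.  Scores
    are canonicalized to higher-is-better; ``score_sense='lower'`` negates a
    penalty-style score on load.  Returns (reads, report) where report counts
    skipped unmapped records.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".tsv":
        return _load_tsv_alignments(path)
    mode = "rb" if ext == ".bam" else "r"
    reads: List[MappedRead] = []
    report = {"n_records": 0, "n_unmapped": 0, "n_loaded": 0}
    with pysam.AlignmentFile(path, mode, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            report["n_records"] += 1
            if rec.is_unmapped or rec.query_sequence is None:
                report["n_unmapped"] += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            length = rec.query_length
            five_prime = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            seq_as_sequenced = (
                revcomp(rec.query_sequence) if rec.is_reverse else rec.query_sequence
            )
            mism = _mismatch_cycles(rec, genome, length)
            if unique_tag is not None and rec.has_tag(unique_tag):
                unique = int(rec.get_tag(unique_tag)) == 1
            elif unique_mapq is not None:
                unique = rec.mapping_quality >= unique_mapq
            else:
                unique = True
            if rec.has_tag(score_tag):
                score = float(rec.get_tag(score_tag))
                if score_sense == "lower":
                    score = -score
            else:
                score = float(length - len(mism))
            reads.append(
                MappedRead(
                    rec.query_name, rec.reference_name, strand, five_prime,
                    length, seq_as_sequenced, len(mism), mism, unique, score,
                )
            )
            report["n_loaded"] += 1
    return reads, report


def _mismatch_cycles(
    rec: "pysam.AlignedSegment", genome: Optional[Genome], length: int
) -> List[int]:
    """Read-cycle indices of mismatches, from MD or a reference genome."""
    has_md = rec.has_tag("MD")
    if not has_md and genome is None:
        raise FormatError(
            f"read {rec.query_name!r}: no MD tag and no genome to compare against"
        )
    cycles: List[int] = []
    if has_md:
        pairs = rec.get_aligned_pairs(with_seq=True)
        for qpos, _rpos, ref_base in pairs:
            if qpos is None or ref_base is None:
                continue
            if ref_base.islower():  # pysam lowercases mismatched reference bases
                cycles.append(length - 1 - qpos if rec.is_reverse else qpos)
    else:
        contig_seq = genome.contigs[rec.reference_name]
        for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
            if rec.query_sequence[qpos].upper() != contig_seq[rpos].upper():
                cycles.append(length - 1 - qpos if rec.is_reverse else qpos)
    return sorted(cycles)


def _load_tsv_alignments(path: str) -> Tuple[List[MappedRead], Dict[str, int]]:
    reads: List[MappedRead] = []
    report = {"n_records": 0, "n_unmapped": 0, "n_loaded": 0}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise FormatError(f"{path}: bad TSV header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            report["n_records"] += 1
            mism = [int(x) for x in f[7].split(",") if x != ""]
            reads.append(
                MappedRead(
                    f[0], f[1], f[2], int(f[3]), int(f[4]), f[5],
                    int(f[6]), mism, f[8] == "1", float(f[9]),
                )
            )
            report["n_loaded"] += 1
    return reads, report


def write_alignments_tsv(reads: Iterable[MappedRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.read_id, r.contig, r.strand, r.five_prime_pos, r.length,
                        r.sequence, r.n_mismatches,
                        ",".join(str(c) for c in r.mismatch_positions),
                        int(r.unique), r.align_score,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Per-strand sparse tracks (bedGraph)

TrackData = Mapping[Tuple[str, str], Mapping[int, float]]

_STRAND_NAME = {"+": "plus", "-": "minus"}


def write_track(data: TrackData, prefix: str) -> Dict[str, str]:
    """Write a per-(contig, strand) sparse position->value map as one
    bedGraph file per strand; adjacent equal-valued positions are merged.
    Returns {strand: path}."""
    paths = {}
    for strand, suffix in _STRAND_NAME.items():
        path = f"{prefix}.{suffix}.bedgraph"
        with open(path, "w") as fh:
            for (contig, s), posmap in sorted(data.items()):
                if s != strand:
                    continue
                for start, end, value in _merge_runs(posmap):
                    fh.write(f"{contig}\t{start}\t{end}\t{value:.10g}\n")
        paths[strand] = path
    return paths


def _merge_runs(posmap: Mapping[int, float]):
    run_start = run_end = None
    run_val = None
    for pos in sorted(posmap):
        val = posmap[pos]
        if run_start is not None and pos == run_end and val == run_val:
            run_end = pos + 1
        else:
            if run_start is not None:
                yield run_start, run_end, run_val
            run_start, run_end, run_val = pos, pos + 1, val
    if run_start is not None:
        yield run_start, run_end, run_val


def read_track(prefix: str) -> Dict[Tuple[str, str], Dict[int, float]]:
    """Inverse of :func:`write_track`."""
    data: Dict[Tuple[str, str], Dict[int, float]] = {}
    for strand, suffix in _STRAND_NAME.items():
        path = f"{prefix}.{suffix}.bedgraph"
        if not os.path.exists(path):
            continue
        with open(path) as fh:
            for line in fh:
                contig, start, end, value = line.rstrip("\n").split("\t")
                posmap = data.setdefault((contig, strand), {})
                for pos in range(int(start), int(end)):
                    posmap[pos] = float(value)
    return data
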